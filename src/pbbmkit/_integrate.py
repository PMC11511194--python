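"""Piecewise ODE integration with hysteretic on/off triggers.

Supersaturation-driven precipitation switches on when the supersaturation
ratio crosses an upper threshold and off when it falls back to unity.
Such hysteresis cannot be expressed as a smooth right-hand side, so the
integration is split into segments at trigger crossings, detected with
solver event functions, and the boolean trigger vector is part of the
piecewise-constant state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["Trigger", "integrate_with_triggers"]


@dataclass
class Trigger:
    """One hysteretic switch.

    ``on_value(t, y)`` > 0 arms the trigger (crossing upward),
    ``off_value(t, y)`` < 0 disarms it (crossing downward).
    """

    on_value: callable
    off_value: callable
    state: bool = False

    def reconcile(self, t, y):
        """Update state from the instantaneous values (start-of-segment)."""
        changed = False
        if not self.state and self.on_value(t, y) > 0:
            self.state, changed = True, True
        elif self.state and self.off_value(t, y) < 0:
            self.state, changed = False, True
        return changed


def integrate_with_triggers(rhs, t_span, y0, t_eval, triggers,
                            method="LSODA", rtol=1e-8, atol=1e-12,
                            max_switches=200, jac=None, **solver_kwargs):
    """Integrate ``rhs(t, y, states)`` over ``t_span`` with trigger switching.

    ``states`` is the tuple of current trigger booleans; ``jac`` (optional)
    has the same signature and returns the Jacobian of ``rhs``. Returns
    ``(t_eval, Y, switch_times)`` with ``Y`` of shape (n_state, n_eval).
    """
    t0, t_end = t_span
    t_eval = np.asarray(t_eval, dtype=float)
    y = np.asarray(y0, dtype=float).copy()
    ts_out, ys_out = [], []
    switch_times = []
    t = t0
    for _ in range(max_switches):
        for trig in triggers:
            trig.reconcile(t, y)
        states = tuple(trig.state for trig in triggers)

        def seg_rhs(tt, yy, _states=states):
            return rhs(tt, yy, _states)

        seg_jac = None
        if jac is not None:
            def seg_jac(tt, yy, _states=states):
                return jac(tt, yy, _states)

        events = []
        for trig in triggers:
            if trig.state:
                ev = (lambda tt, yy, f=trig.off_value: f(tt, yy))
                ev.direction = -1.0
            else:
                ev = (lambda tt, yy, f=trig.on_value: f(tt, yy))
                ev.direction = 1.0
            ev.terminal = True
            events.append(ev)

        mask = (t_eval >= t - 1e-12) & (t_eval <= t_end)
        seg_eval = np.clip(t_eval[mask], t, t_end)
        sol = solve_ivp(seg_rhs, (t, t_end), y, method=method,
                        t_eval=seg_eval if len(seg_eval) else None,
                        events=events if triggers else None,
                        rtol=rtol, atol=atol, jac=seg_jac, **solver_kwargs)
        if not sol.success:
            raise RuntimeError(f"integration failed at t={t:.4g}: {sol.message}")
        stopped_at = t_end
        if sol.status == 1:  # a trigger event fired
            stopped_at = min(
                te[0] for te in sol.t_events if te is not None and len(te)
            )
        seg_t = np.asarray(sol.t, dtype=float)
        seg_y = np.asarray(sol.y, dtype=float) if np.size(sol.y) else \
            np.empty((len(y), 0))
        keep = seg_t <= stopped_at + 1e-12
        ts_out.append(seg_t[keep])
        ys_out.append(seg_y[:, keep] if seg_y.size else seg_y)
        if sol.status == 1:
            # restart from the event point with flipped trigger state
            y = _state_at(sol, stopped_at)
            t = stopped_at
            switch_times.append(t)
            for trig, te in zip(triggers, sol.t_events):
                if te is not None and len(te) and abs(te[0] - t) < 1e-9:
                    trig.state = not trig.state
            if t >= t_end - 1e-12:
                break
        else:
            break
    else:
        raise RuntimeError(
            f"exceeded {max_switches} trigger switches; chattering trigger?"
        )

    t_all = np.concatenate(ts_out) if ts_out else np.array([])
    y_all = np.concatenate(ys_out, axis=1) if ys_out else np.empty((len(y0), 0))
    # deduplicate eval points repeated at segment joins
    out = np.empty((len(y0), len(t_eval)))
    for j, te in enumerate(t_eval):
        idx = np.argmin(np.abs(t_all - te)) if len(t_all) else None
        if idx is None or abs(t_all[idx] - te) > 1e-6:
            raise RuntimeError(f"missing output point t={te}")
        out[:, j] = y_all[:, idx]
    return t_eval, out, switch_times


def _state_at(sol, t_event):
    for te, ye in zip(sol.t_events, sol.y_events):
        if te is not None and len(te) and abs(te[0] - t_event) < 1e-9:
            return np.asarray(ye[0], dtype=float).copy()
    return sol.y[:, -1].copy()
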