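"""Turn a sparse implicit null vector back into an explicit rational ODE.

From Theta(x) xi_a + dx/dt * Theta(x) xi_b = 0 the explicit rate law is

    dx_k/dt = -(Theta(x) xi_a) / (Theta(x) xi_b),

so the numerator coefficients are -xi_a and the denominator coefficients are
xi_b.  The overall scale of a null vector is arbitrary; models are reported
with the largest-magnitude denominator coefficient rescaled to one (a
deterministic, scale-free pivot).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .obslib import Term, evaluate_monomials
from . import models as _models

__all__ = [
    "RationalModel",
    "split",
    "recover_named_parameters",
    "simulate_identified",
]


@dataclass
class RationalModel:
    """Explicit rational rate law for one state equation."""

    state_index: int
    monomials: list[Term]          # plain monomial terms (shared by N and D)
    numerator: np.ndarray          # coefficients of N over `monomials`
    denominator: np.ndarray        # coefficients of D over `monomials`
    pivot: int                     # index (into monomials) of the term scaled to 1
    state_names: list[str] | None = None

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Rate dx_k/dt at one state row or a (p, n) matrix of rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        theta = evaluate_monomials(X, self.monomials)
        den = theta @ self.denominator
        if np.any(den == 0.0):
            raise ZeroDivisionError("denominator vanishes at an evaluation point")
        out = (theta @ self.numerator) / den
        return out if out.size > 1 else float(out[0])

    def equation_string(self) -> str:
        names = self.state_names

        def side(coeffs):
            parts = []
            for c, t in zip(coeffs, self.monomials):
                if c == 0.0:
                    continue
                mono = t.as_string(names)
                parts.append(f"{c:+.6g}" if mono == "1" else f"{c:+.6g}*{mono}")
            return " ".join(parts) if parts else "0"

        lhs = f"dx{self.state_index + 1}/dt"
        if names:
            lhs = f"d{names[self.state_index]}/dt"
        return f"{lhs} = ({side(self.numerator)}) / ({side(self.denominator)})"

    def to_json_dict(self) -> dict:
        return {
            "state_index": self.state_index,
            "terms": [t.as_string(self.state_names) for t in self.monomials],
            "numerator": self.numerator.tolist(),
            "denominator": self.denominator.tolist(),
            "pivot": int(self.pivot),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def split(nv, terms: Sequence[Term], state_index: int | None = None,
          state_names: Sequence[str] | None = None) -> RationalModel:
    """Regroup a (sparsified) null vector into numerator and denominator.

    ``terms`` is the full library ordering (plain monomials then their
    derivative-paired twins).  At least one derivative-paired coefficient
    must survive, otherwise no denominator exists and the relation is not a
    rate law.
    """
    if hasattr(nv, "xi"):
        xi = nv.xi
    elif hasattr(nv, "coefficients"):
        xi = nv.coefficients
    else:
        xi = np.asarray(nv, dtype=float)
    half = len(terms) // 2
    if len(xi) != len(terms):
        raise ValueError("coefficient vector does not match the term ordering")
    xi_a, xi_b = xi[:half], xi[half:]
    if not np.any(xi_b != 0.0):
        raise ValueError("all derivative-paired coefficients are zero: the relation "
                         "constrains only the states and defines no rate law")
    num, den = -xi_a.copy(), xi_b.copy()
    pivot = int(np.argmax(np.abs(den)))
    scale = den[pivot]
    return RationalModel(
        state_index=state_index if state_index is not None else getattr(nv, "state_index", 0),
        monomials=list(terms[:half]),
        numerator=num / scale,
        denominator=den / scale,
        pivot=pivot,
        state_names=list(state_names) if state_names else None,
    )


# --------------------------------------------------------------------------
# model-specific coefficient -> named-parameter maps

def _coeff(rm: RationalModel, which: str, expo: tuple) -> float:
    vec = rm.numerator if which == "N" else rm.denominator
    for c, t in zip(vec, rm.monomials):
        if t.exponents == expo:
            return float(c)
    return 0.0


def _expected_support(model_id: str, k: int, degree: int) -> set[int]:
    return _models.implicit_truth(model_id, k, degree).support


def _check_support(model_id: str, rm: RationalModel, k: int) -> None:
    degree = max(t.degree for t in rm.monomials)
    truth = _models.implicit_truth(model_id, k, degree)
    half = len(rm.monomials)
    got = {i for i in range(half) if rm.numerator[i] != 0.0}
    got |= {half + i for i in range(half) if rm.denominator[i] != 0.0}
    want = truth.support
    if got != want:
        terms = truth.terms
        missing = sorted(want - got)
        spurious = sorted(got - want)
        raise ValueError(
            f"support mismatch for {model_id} state {k + 1}: "
            f"missing terms {[str(terms[i]) for i in missing]}, "
            f"spurious terms {[str(terms[i]) for i in spurious]}"
        )


def recover_named_parameters(model_id: str, rm: RationalModel,
                             k: int | None = None, check: bool = True) -> dict[str, float]:
    """Solve the coefficient-to-parameter map of a benchmark rate law.

    The map normalises the model to the textbook form of the rate law (e.g.
    denominator Km + x for Michaelis–Menten) before reading off parameters,
    so the result does not depend on the reporting pivot.
    """
    k = rm.state_index if k is None else k
    if check:
        _check_support(model_id, rm, k)
    n = _coeff  # shorthand
    if model_id == "mm":
        s = 1.0 / _coeff(rm, "D", (1,))           # make D = Km + x
        Km = _coeff(rm, "D", (0,)) * s
        jx = n(rm, "N", (0,)) * s / Km            # N = jx*Km + (jx - Vmax) x
        Vmax = jx - n(rm, "N", (1,)) * s
        return {"jx": jx, "Vmax": Vmax, "Km": Km}
    if model_id == "competence":
        if k == 0:
            # D = (a3 + x1^2)(1 + x1 + x2): coefficient of x1^3 is 1
            s = 1.0 / _coeff(rm, "D", (3, 0))
            a3 = _coeff(rm, "D", (0, 0)) * s
            a1 = n(rm, "N", (0, 0)) * s / a3
            a2 = n(rm, "N", (2, 0)) * s - a1
            return {"a1": a1, "a2": a2, "a3": a3}
        # D = (1 + b2 x1^5)(1 + x1 + x2): constant coefficient is 1
        s = 1.0 / _coeff(rm, "D", (0, 0))
        b2 = _coeff(rm, "D", (5, 0)) * s
        b1 = n(rm, "N", (0, 0)) * s
        return {"b1": b1, "b2": b2}
    if model_id == "penicillin":
        # D = Kp + x2 + x2^2/K1 over (x1, x2, x4)
        s = 1.0 / _coeff(rm, "D", (0, 1, 0))
        Kp = _coeff(rm, "D", (0, 0, 0)) * s
        K1 = 1.0 / (_coeff(rm, "D", (0, 2, 0)) * s)
        mu_p = n(rm, "N", (0, 1, 1)) * s
        K = -n(rm, "N", (1, 1, 0)) * s
        return {"mu_p": mu_p, "Kp": Kp, "K": K, "K1": K1}
    if model_id == "glycolysis":
        return _glycolysis_named(rm, k)
    raise ValueError(f"unknown model '{model_id}'")


def _glycolysis_named(rm: RationalModel, k: int) -> dict[str, float]:
    def e(i: int, p: int = 1) -> tuple:
        out = [0] * 7
        out[i] = p
        return tuple(out)

    def e2(i: int, j: int) -> tuple:
        out = [0] * 7
        out[i] += 1
        out[j] += 1
        return tuple(out)

    N = lambda expo: _coeff(rm, "N", expo)
    D = lambda expo: _coeff(rm, "D", expo)
    if k == 0:
        s = 1.0 / D((0,) * 7)                     # D = 1 + c3 x6^4
        return {"c1": N((0,) * 7) * s, "c2": N(e2(0, 5)) * s, "c3": D(e(5, 4)) * s}
    if k == 1:
        s = 1.0 / D((0,) * 7)
        return {"d1": N(e2(0, 5)) * s, "d2": D(e(5, 4)) * s,
                "d3": N(e(1)) * s, "d4": N(e2(1, 6)) * s}
    if k == 2:
        s = 1.0 / D((0,) * 7)
        return {"e1": N(e(1)) * s, "e2": N(e(2)) * s,
                "e3": N(e2(1, 6)) * s, "e4": N(e2(2, 5)) * s}
    if k == 3:
        s = 1.0 / D((0,) * 7)
        return {"f1": N(e(2)) * s, "f2": N(e(3)) * s, "f3": N(e(4)) * s,
                "f4": N(e2(2, 5)) * s, "f5": N(e2(3, 6)) * s}
    if k == 4:
        s = 1.0 / D((0,) * 7)
        return {"g1": N(e(3)) * s, "g2": N(e(4)) * s}
    if k == 5:
        s = 1.0 / D((0,) * 7)
        return {"h1": N(e2(0, 5)) * s, "h2": D(e(5, 4)) * s, "h3": N(e(2)) * s,
                "h4": N(e2(2, 5)) * s, "h5": N(e(5)) * s}
    if k == 6:
        s = 1.0 / D((0,) * 7)
        return {"j1": N(e(1)) * s, "j2": N(e2(1, 6)) * s, "j3": N(e2(3, 6)) * s}
    raise ValueError("glycolysis has seven states")


def simulate_identified(
    rational_models: Sequence[RationalModel],
    x0: Sequence[float],
    t_eval: np.ndarray,
    rtol: float = 1e-12,
    atol: float = 1e-12,
    drivers: dict[int, Callable[[float], float]] | None = None,
) -> np.ndarray:
    """Integrate a system assembled from identified rate laws.

    ``rational_models`` provides one model per *identified* state equation;
    states not covered must be supplied through ``drivers`` (index ->
    function of time).  Raises if a denominator crosses zero along the
    trajectory, reporting the crossing time.
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    by_state = {rm.state_index: rm for rm in rational_models}
    missing = set(range(n)) - set(by_state) - set(drivers or {})
    if missing:
        raise ValueError(f"no rate law or driver for states {sorted(missing)}")

    lib_states: dict[int, list[int]] = {}
    for k, rm in by_state.items():
        m = len(rm.monomials[0].exponents)
        lib_states[k] = list(range(m))  # models are expressed over their own state slice

    def f(t: float, x: np.ndarray) -> np.ndarray:
        dx = np.zeros(n)
        for k in range(n):
            if k in by_state:
                rm = by_state[k]
                m = len(rm.monomials[0].exponents)
                dx[k] = rm.evaluate(x[:m])
            else:
                dx[k] = drivers[k](t)
        return dx

    def den_event_factory(rm: RationalModel):
        def ev(t, x):
            m = len(rm.monomials[0].exponents)
            theta = evaluate_monomials(np.atleast_2d(x[:m]), rm.monomials)
            return float((theta @ rm.denominator)[0])
        ev.terminal = True
        return ev

    events = [den_event_factory(rm) for rm in rational_models]
    sol = solve_ivp(f, (t_eval[0], t_eval[-1]), x0, t_eval=t_eval,
                    method="DOP853", rtol=rtol, atol=atol, events=events)
    for ev_t in sol.t_events or []:
        if len(ev_t):
            raise ZeroDivisionError(
                f"identified-model denominator crosses zero at t = {ev_t[0]:.6g}"
            )
    if not sol.success:
        raise RuntimeError(f"integration of the identified model failed: {sol.message}")
    return sol.y.T
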