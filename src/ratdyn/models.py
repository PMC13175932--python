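"""Benchmark biochemical systems and synthetic data generation.

Four systems with rational rate laws, spanning one to seven states:

``mm``
    Michaelis–Menten substrate turnover with constant influx,
    dx/dt = jx - Vmax*x/(Km + x).
``competence``
    Two-protein (ComK/ComS) competence circuit of *Bacillus subtilis*:
    Hill-type positive feedback on ComK, ComK-repressed ComS production and
    shared MecA-mediated degradation.
``penicillin``
    Batch penicillin production: substrate-inhibited specific production rate
    driving product accumulation, with first-order hydrolysis, on top of a
    Contois biomass/substrate subsystem that supplies the driving signals.
``glycolysis``
    The seven-species yeast glycolysis oscillator (glucose, triose pool,
    1,3-BPG, pyruvate/acetaldehyde pool, external coupling species, ATP,
    NADH), with quartic ATP inhibition of the PFK step.

Each system exposes its exact right-hand side, the implicit ("cleared
denominator") expansion of each rate law over the monomial basis, and a
trajectory simulator that produces stacked :class:`Dataset` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .obslib import Term, library_terms

__all__ = [
    "Dataset",
    "BenchmarkSpec",
    "ImplicitTruth",
    "MODEL_IDS",
    "default_params",
    "benchmark_spec",
    "rhs",
    "simulate",
    "implicit_truth",
    "true_named_parameters",
    "add_noise",
]

MODEL_IDS = ("mm", "competence", "penicillin", "glycolysis")


# --------------------------------------------------------------------------
# containers

@dataclass
class Dataset:
    """Stacked trajectories: states, sampling times, derivatives.

    ``trajectory_index[i]`` maps row ``i`` to the trajectory it came from;
    within a trajectory the times are strictly increasing.
    """

    X: np.ndarray
    t: np.ndarray
    xdot: np.ndarray | None
    trajectory_index: np.ndarray
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.t = np.asarray(self.t, dtype=float)
        self.trajectory_index = np.asarray(self.trajectory_index, dtype=int)
        p = self.X.shape[0]
        if self.t.shape[0] != p or self.trajectory_index.shape[0] != p:
            raise ValueError("X, t and trajectory_index must have equal row counts")
        if self.xdot is not None:
            self.xdot = np.atleast_2d(np.asarray(self.xdot, dtype=float))
            if self.xdot.shape != self.X.shape:
                raise ValueError("xdot must match the shape of X")
        for tr in np.unique(self.trajectory_index):
            tt = self.t[self.trajectory_index == tr]
            if np.any(np.diff(tt) <= 0):
                raise ValueError(f"times within trajectory {tr} must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_states(self) -> int:
        return self.X.shape[1]

    @property
    def trajectories(self) -> list[int]:
        return list(np.unique(self.trajectory_index))

    def rows_of(self, trajectory: int) -> np.ndarray:
        return np.where(self.trajectory_index == trajectory)[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        names = self.state_names or [f"x{i + 1}" for i in range(self.n_states)]
        data = {"t": self.t, "trajectory_id": self.trajectory_index}
        for i, n in enumerate(names):
            data[n] = self.X[:, i]
        if self.xdot is not None:
            for i, n in enumerate(names):
                data[f"d{n}"] = self.xdot[:, i]
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        import pandas as pd

        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("t", "trajectory_id") and not c.startswith("d")]
        dnames = [f"d{n}" for n in names]
        xdot = df[dnames].to_numpy() if all(d in df.columns for d in dnames) else None
        return cls(
            X=df[names].to_numpy(),
            t=df["t"].to_numpy(),
            xdot=xdot,
            trajectory_index=df["trajectory_id"].to_numpy(),
            state_names=names,
        )


@dataclass
class BenchmarkSpec:
    """Everything needed to generate a benchmark dataset."""

    model_id: str
    params: dict[str, float]
    state_names: list[str]
    library_states: list[int]
    degree: int
    t_span: tuple[float, float]
    dt: float
    n_trajectories: int
    ic_low: np.ndarray
    ic_high: np.ndarray
    dispersion: float = 0.0  # lognormal sd of multiplicative state dispersion
    ic_values: list | None = None  # explicit initial conditions (overrides the ranges)
    rtol: float = 1e-12
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if not set(self.library_states) <= set(range(len(self.state_names))):
            raise ValueError("library_states must be a subset of the model states")
        self.ic_low = np.asarray(self.ic_low, dtype=float)
        self.ic_high = np.asarray(self.ic_high, dtype=float)

    @property
    def t_eval(self) -> np.ndarray:
        t0, t1 = self.t_span
        n = int(round((t1 - t0) / self.dt))
        return t0 + self.dt * np.arange(n + 1)

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.__dict__.items()}
        d["t_span"] = list(self.t_span)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BenchmarkSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["t_span"] = tuple(d["t_span"])
        return cls(**d)


@dataclass
class ImplicitTruth:
    """True coefficients of dx_k/dt * D(x) - N(x) = 0 over a term ordering."""

    state_index: int
    coefficients: np.ndarray
    terms: list[Term]

    @property
    def support(self) -> set[int]:
        return set(np.where(self.coefficients != 0.0)[0])

    @property
    def unit(self) -> np.ndarray:
        """Unit-norm coefficients with the sign convention (largest entry positive)."""
        xi = self.coefficients / np.linalg.norm(self.coefficients)
        if xi[int(np.argmax(np.abs(xi)))] < 0:
            xi = -xi
        return xi


# --------------------------------------------------------------------------
# polynomial dictionaries (exponent tuple -> coefficient) for exact expansions

def _pmul(a: Mapping[tuple, float], b: Mapping[tuple, float]) -> dict[tuple, float]:
    out: dict[tuple, float] = {}
    for ea, ca in a.items():
        for eb, cb in b.items():
            e = tuple(x + y for x, y in zip(ea, eb))
            out[e] = out.get(e, 0.0) + ca * cb
    return out


def _padd(*polys: Mapping[tuple, float]) -> dict[tuple, float]:
    out: dict[tuple, float] = {}
    for p in polys:
        for e, c in p.items():
            out[e] = out.get(e, 0.0) + c
    return {e: c for e, c in out.items() if c != 0.0}


def _pscale(a: Mapping[tuple, float], s: float) -> dict[tuple, float]:
    return {e: s * c for e, c in a.items()}


def _mono(n: int, i: int, p: int = 1) -> dict[tuple, float]:
    e = [0] * n
    e[i] = p
    return {tuple(e): 1.0}


def _const(n: int, c: float = 1.0) -> dict[tuple, float]:
    return {tuple([0] * n): c}


# --------------------------------------------------------------------------
# model definitions

def _mm_defaults() -> dict[str, float]:
    return {"jx": 0.6, "Vmax": 1.5, "Km": 0.3}


def _mm_rhs(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    return np.array([p["jx"] - p["Vmax"] * x[0] / (p["Km"] + x[0])])


def _mm_nd(k: int, p: Mapping[str, float]):
    if k != 0:
        raise ValueError("mm has a single state")
    # dx/dt (Km + x) = jx*Km + (jx - Vmax) x
    D = {(0,): p["Km"], (1,): 1.0}
    N = {(0,): p["jx"] * p["Km"], (1,): p["jx"] - p["Vmax"]}
    return N, D


def _competence_defaults() -> dict[str, float]:
    return {"a1": 0.004, "a2": 0.07, "a3": 0.04, "b1": 0.82, "b2": 1854.5}


def _competence_rhs(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    x1, x2 = x
    shared = 1.0 + x1 + x2
    return np.array(
        [
            p["a1"] + p["a2"] * x1**2 / (p["a3"] + x1**2) - x1 / shared,
            p["b1"] / (1.0 + p["b2"] * x1**5) - x2 / shared,
        ]
    )


def _competence_nd(k: int, p: Mapping[str, float]):
    n = 2
    shared = _padd(_const(n), _mono(n, 0), _mono(n, 1))  # 1 + x1 + x2
    if k == 0:
        hill = _padd(_const(n, p["a3"]), _mono(n, 0, 2))  # a3 + x1^2
        D = _pmul(hill, shared)
        N = _padd(
            _pscale(D, p["a1"]),
            _pscale(_pmul(_mono(n, 0, 2), shared), p["a2"]),
            _pscale(_pmul(_mono(n, 0), hill), -1.0),
        )
    elif k == 1:
        rep = _padd(_const(n), _pscale(_mono(n, 0, 5), p["b2"]))  # 1 + b2 x1^5
        D = _pmul(rep, shared)
        N = _padd(_pscale(shared, p["b1"]), _pscale(_pmul(_mono(n, 1), rep), -1.0))
    else:
        raise ValueError("competence has two states")
    return N, D


def _penicillin_defaults() -> dict[str, float]:
    # production/hydrolysis (identified) + Contois growth subsystem (drivers)
    return {
        "mu_p": 0.005,
        "Kp": 0.0002,
        "K1": 0.1,
        "K": 0.04,
        "F": 0.0,
        "Kop": 0.0,
        "mu_x": 0.092,
        "Kx": 0.15,
        "Yxs": 0.45,
        "Yps": 0.90,
        "mx": 0.014,
        "Ks_m": 0.05,
    }


def _penicillin_rhs(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    x1, x2, x4, x5 = x  # penicillin, substrate, biomass, volume
    if p["F"] != 0.0 and x5 == 0.0:
        raise ZeroDivisionError("penicillin dilution term undefined: volume x5 = 0 with F != 0")
    spec_prod = p["mu_p"] * x2 / (p["Kp"] + x2 * (1.0 + x2 / p["K1"]))
    mu = p["mu_x"] * x2 / (p["Kx"] * x4 + x2)
    dil = p["F"] / x5 if p["F"] != 0.0 else 0.0
    return np.array(
        [
            spec_prod * x4 - p["K"] * x1 - x1 * dil,
            -mu * x4 / p["Yxs"] - spec_prod * x4 / p["Yps"] - p["mx"] * x4 * x2 / (p["Ks_m"] + x2),
            mu * x4 - x4 * dil,
            p["F"],
        ]
    )


def _penicillin_nd(k: int, p: Mapping[str, float]):
    if k != 0:
        raise ValueError("only the penicillin-concentration equation (k=0) is rational "
                         "over the library states (x1, x2, x4)")
    if p["F"] != 0.0:
        raise ValueError("the implicit expansion is stated for the batch case F = 0")
    n = 3  # library states: x1, x2, x4
    # D = Kp + x2 + x2^2/K1 ; N = mu_p x2 x4 - K x1 D
    D = _padd(_const(n, p["Kp"]), _mono(n, 1), _pscale(_mono(n, 1, 2), 1.0 / p["K1"]))
    x2x4 = _pmul(_mono(n, 1), _mono(n, 2))
    N = _padd(_pscale(x2x4, p["mu_p"]), _pscale(_pmul(_mono(n, 0), D), -p["K"]))
    return N, D


def _glycolysis_defaults() -> dict[str, float]:
    h = 13.6769  # 1/K1^4 of the PFK Hill term
    return {
        "c1": 2.5, "c2": -100.0, "c3": h,
        "d1": 200.0, "d2": h, "d3": -6.0, "d4": -6.0,
        "e1": 6.0, "e2": -64.0, "e3": -6.0, "e4": 16.0,
        "f1": 64.0, "f2": -13.0, "f3": 13.0, "f4": -16.0, "f5": -100.0,
        "g1": 1.3, "g2": -3.1,
        "h1": -200.0, "h2": h, "h3": 128.0, "h4": -32.0, "h5": -1.28,
        "j1": 6.0, "j2": -18.0, "j3": -100.0,
    }


def _glycolysis_rhs(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    x1, x2, x3, x4, x5, x6, x7 = x
    hill = x1 * x6 / (1.0 + p["c3"] * x6**4)
    return np.array(
        [
            p["c1"] + p["c2"] * hill,
            p["d1"] * hill + p["d3"] * x2 + p["d4"] * x2 * x7,
            p["e1"] * x2 + p["e2"] * x3 + p["e3"] * x2 * x7 + p["e4"] * x3 * x6,
            p["f1"] * x3 + p["f2"] * x4 + p["f3"] * x5 + p["f4"] * x3 * x6 + p["f5"] * x4 * x7,
            p["g1"] * x4 + p["g2"] * x5,
            p["h1"] * hill + p["h3"] * x3 + p["h5"] * x6 + p["h4"] * x3 * x6,
            p["j1"] * x2 + p["j2"] * x2 * x7 + p["j3"] * x4 * x7,
        ]
    )


def _glycolysis_nd(k: int, p: Mapping[str, float]):
    n = 7
    hill_den = _padd(_const(n), _pscale(_mono(n, 5, 4), p["c3"]))  # 1 + c3 x6^4
    x1x6 = _pmul(_mono(n, 0), _mono(n, 5))

    def poly(pairs):  # [(coeff_name, poly)]
        return _padd(*[_pscale(q, p[c]) for c, q in pairs])

    one = _const(n)
    if k == 0:
        N = _padd(_pscale(hill_den, p["c1"]), _pscale(x1x6, p["c2"]))
        return N, hill_den
    if k == 1:
        rest = poly([("d3", _mono(n, 1)), ("d4", _pmul(_mono(n, 1), _mono(n, 6)))])
        N = _padd(_pscale(x1x6, p["d1"]), _pmul(rest, hill_den))
        return N, hill_den
    if k == 2:
        N = poly([("e1", _mono(n, 1)), ("e2", _mono(n, 2)),
                  ("e3", _pmul(_mono(n, 1), _mono(n, 6))), ("e4", _pmul(_mono(n, 2), _mono(n, 5)))])
        return N, one
    if k == 3:
        N = poly([("f1", _mono(n, 2)), ("f2", _mono(n, 3)), ("f3", _mono(n, 4)),
                  ("f4", _pmul(_mono(n, 2), _mono(n, 5))), ("f5", _pmul(_mono(n, 3), _mono(n, 6)))])
        return N, one
    if k == 4:
        N = poly([("g1", _mono(n, 3)), ("g2", _mono(n, 4))])
        return N, one
    if k == 5:
        rest = poly([("h3", _mono(n, 2)), ("h5", _mono(n, 5)),
                     ("h4", _pmul(_mono(n, 2), _mono(n, 5)))])
        N = _padd(_pscale(x1x6, p["h1"]), _pmul(rest, hill_den))
        return N, hill_den
    if k == 6:
        N = poly([("j1", _mono(n, 1)), ("j2", _pmul(_mono(n, 1), _mono(n, 6))),
                  ("j3", _pmul(_mono(n, 3), _mono(n, 6)))])
        return N, one
    raise ValueError("glycolysis has seven states")


_RHS: dict[str, Callable] = {
    "mm": _mm_rhs,
    "competence": _competence_rhs,
    "penicillin": _penicillin_rhs,
    "glycolysis": _glycolysis_rhs,
}
_ND: dict[str, Callable] = {
    "mm": _mm_nd,
    "competence": _competence_nd,
    "penicillin": _penicillin_nd,
    "glycolysis": _glycolysis_nd,
}
_DEFAULTS: dict[str, Callable] = {
    "mm": _mm_defaults,
    "competence": _competence_defaults,
    "penicillin": _penicillin_defaults,
    "glycolysis": _glycolysis_defaults,
}


def default_params(model_id: str) -> dict[str, float]:
    _check_model(model_id)
    return _DEFAULTS[model_id]()


def _check_model(model_id: str) -> None:
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model '{model_id}'; choose from {MODEL_IDS}")


def benchmark_spec(model_id: str, **overrides) -> BenchmarkSpec:
    """Default benchmark configuration for a model.

    Sampling grids match the published study conditions: mm on t in [0, 20] s
    at 1 s from two initial substrate levels; competence on [0, 50] s at 1 s
    from 20 random starts; penicillin over 100 h sampled hourly from 20
    batches; glycolysis on [0, 5] at 0.1 from 450 random starts.
    """
    _check_model(model_id)
    params = default_params(model_id)
    if model_id == "mm":
        spec = BenchmarkSpec(
            model_id="mm", params=params, state_names=["x"], library_states=[0],
            degree=4, t_span=(0.0, 20.0), dt=1.0, n_trajectories=2,
            ic_low=np.array([0.5]), ic_high=np.array([2.0]),
            ic_values=[[0.5], [2.0]],
        )
    elif model_id == "competence":
        spec = BenchmarkSpec(
            model_id="competence", params=params, state_names=["x1", "x2"],
            library_states=[0, 1], degree=6, t_span=(0.0, 50.0), dt=1.0,
            n_trajectories=20, ic_low=np.zeros(2), ic_high=np.ones(2),
        )
    elif model_id == "penicillin":
        spec = BenchmarkSpec(
            model_id="penicillin", params=params,
            state_names=["x1", "x2", "x4", "x5"], library_states=[0, 1, 2],
            degree=3, t_span=(0.0, 100.0), dt=1.0, n_trajectories=20,
            ic_low=np.array([0.0, 25.0, 0.05, 100.0]),
            ic_high=np.array([0.2, 35.0, 0.15, 100.0]),
        )
    else:  # glycolysis
        # per-species initial ranges of the reference oscillator study
        spec = BenchmarkSpec(
            model_id="glycolysis", params=params,
            state_names=[f"x{i + 1}" for i in range(7)],
            library_states=list(range(7)), degree=6, t_span=(0.0, 5.0), dt=0.1,
            n_trajectories=450,
            ic_low=np.array([0.15, 0.19, 0.04, 0.10, 0.05, 0.14, 0.08]),
            ic_high=np.array([1.60, 2.16, 0.20, 0.35, 0.10, 2.67, 0.30]),
            dispersion=0.4,
        )
    if overrides:
        spec = replace(spec, **overrides)
    return spec


def rhs(model_id: str, x: Sequence[float], params: Mapping[str, float] | None = None) -> np.ndarray:
    """Exact right-hand side of a benchmark model at state ``x``."""
    _check_model(model_id)
    p = dict(default_params(model_id))
    if params:
        p.update(params)
    x = np.asarray(x, dtype=float)
    return _RHS[model_id](x, p)


def rhs_matrix(model_id: str, X: np.ndarray, params: Mapping[str, float] | None = None) -> np.ndarray:
    """Row-wise exact RHS evaluation on a (p, n) state matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([rhs(model_id, row, params) for row in X])


def simulate(spec: BenchmarkSpec, seed: int | None = 0) -> Dataset:
    """Integrate the benchmark from sampled initial conditions.

    Derivatives are exact RHS evaluations at the recorded states, so the
    implicit identity holds to round-off regardless of integration accuracy.
    If ``spec.dispersion > 0`` the recorded states are multiplied by
    lognormal factors exp(dispersion * z), z ~ N(0, 1), before the derivative
    evaluation; the (state, derivative) pairs remain exact.
    """
    rng = np.random.default_rng(seed)
    t_eval = spec.t_eval
    f = _RHS[spec.model_id]
    p = spec.params
    blocks, tix = [], []
    for i in range(spec.n_trajectories):
        if spec.ic_values is not None:
            x0 = np.asarray(spec.ic_values[i % len(spec.ic_values)], dtype=float)
        else:
            x0 = rng.uniform(spec.ic_low, spec.ic_high)
        sol = solve_ivp(
            lambda t, x: f(x, p), (t_eval[0], t_eval[-1]), x0,
            t_eval=t_eval, method="DOP853", rtol=spec.rtol, atol=spec.atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed for {spec.model_id} trajectory {i} "
                f"(reached t = {sol.t[-1] if len(sol.t) else t_eval[0]:g}): {sol.message}"
            )
        blocks.append(sol.y.T)
        tix.append(np.full(len(t_eval), i))
    X = np.vstack(blocks)
    if spec.dispersion > 0.0:
        X = X * np.exp(spec.dispersion * rng.standard_normal(X.shape))
    xdot = np.array([f(row, p) for row in X])
    return Dataset(
        X=X,
        t=np.concatenate([t_eval] * spec.n_trajectories),
        xdot=xdot,
        trajectory_index=np.concatenate(tix),
        state_names=list(spec.state_names),
    )


def implicit_truth(
    model_id: str,
    k: int,
    degree: int,
    params: Mapping[str, float] | None = None,
) -> ImplicitTruth:
    """Exact expansion of dx_k/dt * D(x) - N(x) = 0 over the library ordering.

    The coefficient vector lives on :func:`ratdyn.obslib.library_terms` of the
    model's library states at the given degree: derivative-paired entries
    carry D, plain entries carry -N.
    """
    _check_model(model_id)
    p = dict(default_params(model_id))
    if params:
        p.update(params)
    if model_id == "penicillin":
        k_local, n_lib = 0 if k == 0 else k, 3
    else:
        k_local, n_lib = k, len(benchmark_spec(model_id).library_states)
    N, D = _ND[model_id](k_local, p)
    terms = library_terms(n_lib, degree)
    half = len(terms) // 2
    index = {t.exponents: j for j, t in enumerate(terms[:half])}
    max_deg = max(max((sum(e) for e in N), default=0), max((sum(e) for e in D), default=0))
    if max_deg > degree:
        raise ValueError(
            f"term ordering of degree {degree} cannot hold the expansion (needs {max_deg})"
        )
    xi = np.zeros(len(terms))
    for e, c in N.items():
        xi[index[e]] = -c
    for e, c in D.items():
        xi[half + index[e]] = c
    return ImplicitTruth(state_index=k, coefficients=xi, terms=terms)


def true_named_parameters(model_id: str, params: Mapping[str, float] | None = None) -> dict[str, float]:
    """The named parameters a benchmark identification is scored against."""
    _check_model(model_id)
    p = dict(default_params(model_id))
    if params:
        p.update(params)
    if model_id == "mm":
        return {k: p[k] for k in ("jx", "Vmax", "Km")}
    if model_id == "competence":
        return {k: p[k] for k in ("a1", "a2", "a3", "b1", "b2")}
    if model_id == "penicillin":
        return {k: p[k] for k in ("mu_p", "Kp", "K", "K1")}
    names = [f"{c}{i}" for c, m in (("c", 3), ("d", 4), ("e", 4), ("f", 5),
                                    ("g", 2), ("h", 5), ("j", 3)) for i in range(1, m + 1)]
    return {k: p[k] for k in names}


def add_noise(dataset: Dataset, sigma: float, seed: int | None = 0) -> Dataset:
    """Add i.i.d. Gaussian measurement noise to the states.

    Derivatives are invalidated (set to None): they must be re-estimated from
    the noisy states by a derivative policy.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return Dataset(
            X=dataset.X.copy(), t=dataset.t.copy(), xdot=None,
            trajectory_index=dataset.trajectory_index.copy(),
            state_names=list(dataset.state_names),
        )
    rng = np.random.default_rng(seed)
    return Dataset(
        X=dataset.X + sigma * rng.standard_normal(dataset.X.shape),
        t=dataset.t.copy(),
        xdot=None,
        trajectory_index=dataset.trajectory_index.copy(),
        state_names=list(dataset.state_names),
    )
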