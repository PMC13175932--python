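"""Error metrics for identified models.

Three complementary scores:

* structural error — a set-based L0 score of the identified support against
  the true support: 1 - |S_true ∩ S_id| / (|S_true| + |S_id \\ S_true|).
  0 means perfect support recovery; missing and spurious terms both move the
  score toward 1.
* parameter error — relative Euclidean distance between implicit coefficient
  vectors, after unit normalisation and sign alignment (null vectors carry
  no scale or sign).
* relative Frobenius error — ||est - true||_F / ||true||_F over a named
  parameter map (or any aligned array), the headline accuracy number of a
  benchmark run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SupportSet",
    "ErrorReport",
    "structural_error",
    "parameter_error",
    "relative_frobenius",
]


@dataclass
class SupportSet:
    """True and identified supports over a common term universe."""

    s_true: set[int]
    s_identified: set[int]


def structural_error(s: SupportSet | None = None,
                     s_true: Iterable[int] | None = None,
                     s_identified: Iterable[int] | None = None) -> float:
    """L0 structural error in [0, 1]; 0 iff the supports are equal."""
    if s is not None:
        s_true, s_identified = s.s_true, s.s_identified
    st, si = set(s_true), set(s_identified)
    if not st:
        raise ValueError("the true support must be non-empty")
    return 1.0 - len(st & si) / (len(st) + len(si - st))


def parameter_error(xi_true: np.ndarray, xi_est: np.ndarray) -> float:
    """Relative 2-norm error between implicit coefficient vectors.

    Both vectors are unit-normalised first and the sign of the estimate is
    chosen to minimise the error (a null vector is defined up to sign).
    """
    xt = np.asarray(xi_true, dtype=float)
    xe = np.asarray(xi_est, dtype=float)
    if xt.shape != xe.shape:
        raise ValueError("coefficient vectors must have equal length and ordering")
    nt = np.linalg.norm(xt)
    if nt == 0:
        raise ValueError("the true coefficient vector must be nonzero")
    xt = xt / nt
    ne = np.linalg.norm(xe)
    xe = xe / ne if ne > 0 else xe
    return float(min(np.linalg.norm(xt - xe), np.linalg.norm(xt + xe)))


def relative_frobenius(true: Mapping[str, float] | np.ndarray,
                       est: Mapping[str, float] | np.ndarray,
                       sign_insensitive: bool = False) -> float:
    """Frobenius-norm relative error over aligned named parameters.

    Dicts are aligned by key (est must cover every true key); arrays by
    position.  With ``sign_insensitive`` the magnitudes are compared.
    """
    if isinstance(true, Mapping):
        missing = set(true) - set(est)
        if missing:
            raise ValueError(f"estimate is missing parameters: {sorted(missing)}")
        keys = list(true)
        tv = np.array([true[k] for k in keys], dtype=float)
        ev = np.array([est[k] for k in keys], dtype=float)
    else:
        tv = np.asarray(true, dtype=float)
        ev = np.asarray(est, dtype=float)
        if tv.shape != ev.shape:
            raise ValueError("parameter arrays must have equal shapes")
    if sign_insensitive:
        tv, ev = np.abs(tv), np.abs(ev)
    denom = np.linalg.norm(tv)
    if denom == 0:
        raise ValueError("the true parameter vector must be nonzero")
    return float(np.linalg.norm(ev - tv) / denom)


@dataclass
class ErrorReport:
    """Scores of one benchmark identification."""

    structural_error: float
    parameter_error: float
    frobenius_error: float
    per_state: dict[int, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.structural_error <= 1.0:
            raise ValueError("structural error must lie in [0, 1]")

    def to_json_dict(self) -> dict:
        return {
            "structural_error": self.structural_error,
            "parameter_error": self.parameter_error,
            "frobenius_error": self.frobenius_error,
            "per_state": {str(k): v for k, v in self.per_state.items()},
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
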