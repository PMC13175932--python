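"""Observational library construction for implicit rational-dynamics identification.

A rational rate law dx_k/dt = N(x)/D(x) with polynomial numerator and
denominator satisfies the implicit identity

    dx_k/dt * D(x) - N(x) = 0,

which is *linear* in the unknown coefficients of N and D.  The observational
library B stacks, for every sample, all candidate monomials of the states
(the columns of Theta(X)) together with the same monomials multiplied by the
measured derivative dx_k/dt.  Any rational model whose numerator and
denominator fit within the library degree then appears as a null vector of B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "Term",
    "ObservationalLibrary",
    "polynomial_terms",
    "library_terms",
    "evaluate_monomials",
    "build_observational_library",
]


@dataclass(frozen=True, order=False)
class Term:
    """A library column: a monomial over the library states, optionally
    multiplied by the target derivative dx_k/dt."""

    exponents: tuple[int, ...]
    with_derivative: bool = False

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.exponents):
            raise ValueError("monomial exponents must be non-negative")

    @property
    def degree(self) -> int:
        return sum(self.exponents)

    @property
    def key(self) -> tuple:
        """Graded ordering key.  Derivative-paired terms rank above the plain
        monomial of the same degree; used by the minimal-relation extraction."""
        return (self.degree, int(self.with_derivative), self.exponents)

    def as_string(self, state_names: Sequence[str] | None = None, k: int | None = None) -> str:
        names = state_names or [f"x{i + 1}" for i in range(len(self.exponents))]
        parts = []
        for name, e in zip(names, self.exponents):
            if e == 1:
                parts.append(name)
            elif e > 1:
                parts.append(f"{name}^{e}")
        if self.with_derivative:
            parts.append(f"dx{'' if k is None else k + 1}")
        return "*".join(parts) if parts else "1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.as_string()


def polynomial_terms(n_states: int, degree: int) -> list[Term]:
    """All monomials in ``n_states`` variables of total degree <= ``degree``,
    in graded-lexicographic order (constant first).

    The count is C(n_states + degree, degree).
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    terms: list[Term] = []
    for d in range(degree + 1):
        for combo in combinations_with_replacement(range(n_states), d):
            e = [0] * n_states
            for i in combo:
                e[i] += 1
            terms.append(Term(tuple(e), with_derivative=False))
    assert len(terms) == comb(n_states + degree, degree)
    return terms


def library_terms(n_states: int, degree: int) -> list[Term]:
    """Ordered columns of the observational library: all plain monomials
    first, then the same monomials paired with the derivative."""
    mono = polynomial_terms(n_states, degree)
    return mono + [Term(t.exponents, with_derivative=True) for t in mono]


def evaluate_monomials(X: np.ndarray, terms: Sequence[Term]) -> np.ndarray:
    """Evaluate monomial terms row-wise on a (p, n) state matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x states)")
    p, n = X.shape
    cols = np.empty((p, len(terms)))
    # cache powers per state up to the maximum exponent used
    max_pow = [0] * n
    for t in terms:
        for i, e in enumerate(t.exponents):
            max_pow[i] = max(max_pow[i], e)
    powers = [np.vander(X[:, i], max_pow[i] + 1, increasing=True) for i in range(n)]
    for j, t in enumerate(terms):
        c = np.ones(p)
        for i, e in enumerate(t.exponents):
            if e:
                c = c * powers[i][:, e]
        cols[:, j] = c
    return cols


@dataclass
class ObservationalLibrary:
    """The matrix B = [Theta(X), dx_k/dt * Theta(X)] with its column bookkeeping."""

    B: np.ndarray
    terms: list[Term]
    state_index: int
    degree: int
    state_names: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.B.shape[0]

    @property
    def n_columns(self) -> int:
        return self.B.shape[1]

    @property
    def keys(self) -> list[tuple]:
        return [t.key for t in self.terms]

    def term_strings(self) -> list[str]:
        return [t.as_string(self.state_names or None, self.state_index) for t in self.terms]

    def to_dataframe(self):
        """Library as a DataFrame with human-readable column names (debugging)."""
        import pandas as pd

        return pd.DataFrame(self.B, columns=self.term_strings())


def build_observational_library(
    dataset,
    k: int,
    degree: int,
    library_states: Sequence[int] | None = None,
) -> ObservationalLibrary:
    """Build B from a dataset for the rate equation of state ``k``.

    Parameters
    ----------
    dataset
        Object with attributes ``X`` (p x n states), ``xdot`` (p x n
        derivatives) and optionally ``state_names``.
    k
        Index (into the dataset's states) of the equation being identified;
        its derivative multiplies the second block of columns.
    degree
        Maximum total degree of the candidate monomials.
    library_states
        Indices of the states entering the monomials (default: all).
    """
    X = np.asarray(dataset.X, dtype=float)
    if dataset.xdot is None:
        raise ValueError("dataset has no derivatives; apply a derivative policy first")
    xdot = np.asarray(dataset.xdot, dtype=float)
    if not 0 <= k < X.shape[1]:
        raise ValueError(f"state index {k} out of range for {X.shape[1]} states")
    if library_states is None:
        library_states = list(range(X.shape[1]))
    sub = X[:, list(library_states)]
    terms = library_terms(sub.shape[1], degree)
    half = len(terms) // 2
    theta = evaluate_monomials(sub, terms[:half])
    B = np.hstack([theta, xdot[:, k][:, None] * theta])
    names = list(getattr(dataset, "state_names", []) or [])
    lib_names = [names[i] for i in library_states] if names else []
    return ObservationalLibrary(B=B, terms=terms, state_index=k, degree=degree, state_names=lib_names)
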