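"""Null-space identification of implicit rational dynamics.

The observational library B annihilates the implicit coefficient vector of
the true rate law: B @ xi = 0.  The algorithm reduces B by SVD, locates the
cluster of singular values at the numerical-zero floor, extracts the
*minimal* relation from that cluster, and sparsifies it with a fixed small
threshold.

Why an extraction step is needed: whenever the library degree exceeds what
the minimal relation r(x) requires, every polynomial multiple m(x) * r(x)
that still fits inside the library is an equally exact null vector, so the
null space is multi-dimensional and "the" smallest singular vector is an
arbitrary element of that subspace.  Because the leading (highest graded-lex)
term of m * r strictly dominates that of r for every non-constant m, the
generator r is the unique direction in the cluster that survives the
successive elimination of the highest supported coordinates.  The
elimination is performed with orthogonal reflections, one coordinate at a
time, and is therefore deterministic and numerically benign.

The Gram-matrix route (eigendecomposition of B^T B, whose cost is
independent of the sample count) is provided as an alternative compute path;
note that it squares the condition number and can lose the null/range
separation for high-degree libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

__all__ = [
    "NullSpaceOptions",
    "NullVector",
    "gram",
    "null_vector",
    "null_vector_gram",
    "sparsify",
    "identify_library",
    "support_by_gap",
]

_EPS = np.finfo(float).eps


@dataclass
class NullSpaceOptions:
    """Tuning knobs of the null-space pipeline.

    lam
        Sparsification threshold applied to the unit-norm coefficient vector.
    column_scale
        Scale columns to unit max-abs before the decomposition (coefficients
        are unscaled afterwards).  Essential for high-degree libraries.
    cluster
        'auto': size of the numerical-null cluster from the largest
        logarithmic gap among singular values below ``cluster_ceiling`` times
        the largest; an integer forces the cluster size.
    cluster_ceiling
        Relative singular-value ceiling below which cluster boundaries are
        searched.
    extract_rtol
        Relative row-magnitude threshold deciding whether the null cluster
        has support on a coordinate during minimal-relation extraction.
    refine
        Re-estimate coefficients on the detected support (restricted SVD) and
        re-apply the threshold until the support is stable.
    max_iter
        Cap on threshold/re-estimate iterations.
    use_gram
        Compute the null space from eigh(B^T B) instead of svd(B).
    """

    lam: float = 1e-7
    column_scale: bool = True
    cluster: str | int = "auto"
    cluster_ceiling: float = 1e-4
    extract_rtol: float = 1e-6
    refine: bool = True
    max_iter: int = 8
    use_gram: bool = False


@dataclass
class NullVector:
    """A (possibly sparsified) implicit coefficient vector.

    ``xi`` is unit-norm with the sign convention that the largest-magnitude
    entry is positive.  ``singular_values`` is the full spectrum (descending)
    of the decomposition that produced it; ``cluster_size`` the detected
    dimension of the numerical null space.
    """

    xi: np.ndarray
    singular_values: np.ndarray
    cluster_size: int
    chosen_index: int
    support: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.support.size == 0:
            self.support = np.where(self.xi != 0.0)[0]

    @property
    def support_set(self) -> set[int]:
        return set(int(i) for i in self.support)

    def to_json_dict(self) -> dict:
        return {
            "xi": self.xi.tolist(),
            "singular_values": self.singular_values.tolist(),
            "cluster_size": int(self.cluster_size),
            "support": [int(i) for i in self.support],
            "warnings": list(self.warnings),
        }


# --------------------------------------------------------------------------
# primitives

def gram(B: np.ndarray) -> np.ndarray:
    """The observable matrix G = B^T B (q x q), condensing p samples into the
    q-dimensional observable space."""
    B = np.asarray(B, dtype=float)
    if B.size == 0:
        raise ValueError("B must be non-empty")
    return B.T @ B


def _fix_sign(xi: np.ndarray) -> np.ndarray:
    if xi[int(np.argmax(np.abs(xi)))] < 0:
        return -xi
    return xi


def _cluster_size(sv: np.ndarray, ceiling: float) -> tuple[int, list[str]]:
    """Null-cluster size from the largest log-gap below a relative ceiling.

    ``sv`` descending.  Returns 1 (plus a warning) when nothing falls below
    the ceiling.
    """
    q = len(sv)
    smax = sv[0] if sv[0] > 0 else 1.0
    best, best_i = 0.0, None
    for i in range(q - 1):
        lo = sv[i + 1]
        if lo < ceiling * smax:
            ratio = sv[i] / lo if lo > 0 else np.inf
            if ratio > best:
                best, best_i = ratio, i
    if best_i is None:
        return 1, ["no singular value fell below the null ceiling; treating the "
                   "smallest singular direction as the null space"]
    return q - (best_i + 1), []


def _extract_minimal(V0: np.ndarray, keys: list[tuple], rtol: float) -> np.ndarray:
    """Minimal relation from a (q, s) orthonormal null-cluster basis.

    Repeatedly finds the highest-ordered coordinate the span still supports,
    concentrates it into one basis vector with a Householder reflection, and
    drops that vector.  The surviving direction is the generator of the
    polynomial-multiplier family.
    """
    W = V0.copy()
    coord_order = sorted(range(W.shape[0]), key=lambda j: keys[j], reverse=True)
    for j in coord_order:
        s = W.shape[1]
        if s == 1:
            break
        row = W[j, :].copy()
        nr = np.linalg.norm(row)
        row_scale = np.max(np.linalg.norm(W, axis=1))
        if nr < rtol * row_scale:
            continue
        v = row / nr
        sgn = 1.0 if v[0] >= 0 else -1.0
        u = v.copy()
        u[0] += sgn
        u /= np.linalg.norm(u)
        W = W - 2.0 * np.outer(W @ u, u)  # reflection: coordinate j -> column 0
        W = W[:, 1:]
    return W[:, 0]


def _decompose(B: np.ndarray, options: NullSpaceOptions):
    """Scaled SVD (or Gram eigh) of the library; returns (sv desc, V, scale)."""
    B = np.asarray(B, dtype=float)
    q = B.shape[1]
    scale = np.ones(q)
    if options.column_scale:
        scale = np.max(np.abs(B), axis=0)
        scale[scale == 0] = 1.0
    if options.use_gram:
        G = gram(B / scale)
        w, V = scipy.linalg.eigh(G)
        sv = np.sqrt(np.clip(w, 0.0, None))[::-1]
        V = V[:, ::-1]
    else:
        _, sv, Vt = scipy.linalg.svd(B / scale, full_matrices=False, lapack_driver="gesdd")
        V = Vt.T
    return sv, V, scale


def null_vector_gram(G: np.ndarray, keys: list[tuple] | None = None,
                     options: NullSpaceOptions | None = None) -> NullVector:
    """Null vector from the observable matrix G = B^T B (symmetric eigh path)."""
    options = options or NullSpaceOptions()
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, rtol=0, atol=1e-8 * max(1.0, np.abs(G).max())):
        raise ValueError("G must be symmetric")
    w, V = scipy.linalg.eigh(G)
    neg_floor = -1e-12 * max(w[-1], 0.0)
    w = np.where(w < neg_floor, w, np.clip(w, 0.0, None))
    sv = np.sqrt(np.clip(w, 0.0, None))[::-1]
    V = V[:, ::-1]
    return _select(sv, V, np.ones(G.shape[0]), keys, options)


def null_vector(B: np.ndarray, keys: list[tuple] | None = None,
                options: NullSpaceOptions | None = None) -> NullVector:
    """Null vector of the observational library (default: SVD of scaled B)."""
    options = options or NullSpaceOptions()
    sv, V, scale = _decompose(B, options)
    return _select(sv, V, scale, keys, options)


def _select(sv, V, scale, keys, options: NullSpaceOptions) -> NullVector:
    q = V.shape[0]
    warns: list[str] = []
    if isinstance(options.cluster, int):
        s = max(1, min(options.cluster, q))
    else:
        s, w = _cluster_size(sv, options.cluster_ceiling)
        warns += w
    if s > 1:
        if keys is None:
            warns.append(
                f"{s}-dimensional null cluster but no term ordering supplied; "
                "returning the smallest singular direction"
            )
            xi_scaled = V[:, -1]
        else:
            xi_scaled = _extract_minimal(V[:, q - s:], keys, options.extract_rtol)
    else:
        xi_scaled = V[:, -1]
    # tie-break warning for (near-)repeated smallest singular values
    if s == 1 and q >= 2 and sv[-2] > 0 and sv[-1] / sv[-2] > 0.999:
        warns.append("smallest singular value nearly repeated; choosing the last "
                     "singular direction (deterministic tie-break)")
    xi = xi_scaled / scale
    xi = xi / np.linalg.norm(xi)
    xi = _fix_sign(xi)
    return NullVector(
        xi=xi, singular_values=sv.copy(), cluster_size=s,
        chosen_index=q - 1, warnings=warns,
    )


def sparsify(nv: NullVector, lam: float = 1e-7) -> NullVector:
    """Zero entries with magnitude below ``lam`` and re-normalise.

    ``lam`` acts on the unit-norm coefficient vector; its default 1e-7 is the
    fixed small value used throughout the clean benchmarks.
    """
    xi = nv.xi.copy()
    keep = np.abs(xi) >= lam
    if not keep.any():
        raise ValueError("sparsification removed every term (degenerate model)")
    xi[~keep] = 0.0
    xi = _fix_sign(xi / np.linalg.norm(xi))
    return NullVector(
        xi=xi, singular_values=nv.singular_values, cluster_size=nv.cluster_size,
        chosen_index=nv.chosen_index, support=np.where(keep)[0],
        warnings=list(nv.warnings),
    )


def support_by_gap(xi: np.ndarray, guard: float = 10.0) -> np.ndarray:
    """Support from the largest logarithmic gap in the sorted magnitudes.

    Threshold-free rule for noisy estimates: entries above the largest
    magnitude gap are the support.  If no adjacent ratio reaches ``guard``
    the vector is treated as having no separable noise floor and every
    nonzero entry is kept.
    """
    mags = np.sort(np.abs(xi[xi != 0.0]))[::-1]
    if mags.size <= 1:
        return np.where(xi != 0.0)[0]
    ratios = mags[:-1] / mags[1:]
    if ratios.max() < guard:
        return np.where(xi != 0.0)[0]
    thr = mags[int(np.argmax(ratios))]
    return np.where(np.abs(xi) >= thr)[0]


# --------------------------------------------------------------------------
# full pipeline on an observational library

def identify_library(library, options: NullSpaceOptions | None = None) -> NullVector:
    """Sparse implicit model of one rate equation from its library.

    Runs decomposition -> cluster detection -> minimal-relation extraction ->
    lambda-thresholding, then (by default) re-estimates the coefficients on
    the detected support with a restricted SVD and re-applies the threshold
    until the support stops changing.  The restricted re-solve removes the
    conditioning bias of the full decomposition from the surviving
    coefficients.
    """
    options = options or NullSpaceOptions()
    B_full = np.asarray(library.B, dtype=float)
    keys = library.keys
    q = B_full.shape[1]
    cols = np.arange(q)
    first: NullVector | None = None
    for _ in range(max(1, options.max_iter)):
        sub_opts = options if cols.size == q else replace(options, cluster="auto")
        nv = null_vector(B_full[:, cols], [keys[c] for c in cols], sub_opts)
        if first is None:
            first = nv
        full_xi = np.zeros(q)
        full_xi[cols] = nv.xi
        keep = np.abs(full_xi) >= options.lam
        if not keep.any():
            raise ValueError("sparsification removed every term (degenerate model)")
        new_cols = np.where(keep)[0]
        if new_cols.size == cols.size and np.array_equal(new_cols, np.sort(cols)):
            break
        cols = new_cols
        if not options.refine:
            break
    xi = np.zeros(q)
    xi[cols] = full_xi[cols]
    xi = _fix_sign(xi / np.linalg.norm(xi))
    if nv.cluster_size > 1:
        msg = (f"null cluster of dimension {nv.cluster_size} resolved by "
               "minimal-relation extraction")
        if msg not in first.warnings:
            first.warnings.append(msg)
    for w in first.warnings:
        warnings.warn(w, RuntimeWarning, stacklevel=2)
    return NullVector(
        xi=xi, singular_values=first.singular_values, cluster_size=first.cluster_size,
        chosen_index=first.chosen_index, support=np.sort(cols),
        warnings=list(first.warnings),
    )
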