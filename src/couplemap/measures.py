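"""Similarity and communication matrices derived from a structural connectome.

Four predictor matrices operationalize how well functional connectivity can be
explained by structure under different signaling assumptions:

* cosine similarity (CoS) -- resemblance of two regions' structural connection
  profiles; the protocol-free baseline;
* path length (PL) -- shortest weighted path distance (routing);
* communicability (G) -- weighted sum over all walks, longer walks discounted
  factorially (diffusive broadcasting);
* search information (SI) -- bits a random walker needs to follow the shortest
  path (path accessibility).

PL and SI are adjusted after computation (negated by default, so larger always
means "easier communication"); SI is additionally symmetrized.  Communicability
uses the strength-normalized weighted form exp(D^{-1/2} W D^{-1/2}), without
which the matrix exponential overflows for streamline-density-scale weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .datatypes import AnalysisConfig, StructuralConnectome

__all__ = [
    "PredictorMatrix",
    "cosine_similarity_matrix",
    "weight_to_length",
    "path_length_matrix",
    "communicability_matrix",
    "search_information_matrix",
    "search_information_raw",
    "all_predictors",
]

#: unreachable pairs get 1.5x the most extreme finite value, keeping matrix
#: shape while ranking them strictly "hardest to reach"
UNREACHABLE_FACTOR = 1.5


@dataclass
class PredictorMatrix:
    """A similarity or communication matrix derived from one SC."""

    measure: str
    values: np.ndarray
    adjusted: bool = False
    participant_id: str = "unknown"
    meta: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def cosine_similarity_matrix(
    sc: StructuralConnectome, exclude_direct: bool = True
) -> PredictorMatrix:
    """Cosine similarity of structural connectivity profiles.

    Entry (i, j) is the cosine of the angle between SC columns i and j with
    entries i and j removed (default), so the direct i-j weight and the
    (zero) self-weights cannot trivially inflate similarity.  Diagonal is 1.
    Regions without any connection get a zero row/column with a warning.
    """
    w = sc.weights
    # with a zero diagonal, excluding entries i and j leaves the numerator as
    # (W^2)_ij; only the profile norms change between the two variants
    gram = w @ w
    sq_strength = np.sum(w**2, axis=0)
    if exclude_direct:
        ni = sq_strength[:, None] - w**2
        nj = sq_strength[None, :] - w**2
    else:
        ni = np.broadcast_to(sq_strength[:, None], w.shape).copy()
        nj = np.broadcast_to(sq_strength[None, :], w.shape).copy()
    denom = np.sqrt(np.clip(ni, 0.0, None) * np.clip(nj, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(denom > 0, gram / np.where(denom > 0, denom, 1.0), 0.0)
    zero_strength = np.flatnonzero(sq_strength == 0)
    if zero_strength.size:
        warnings.warn(
            f"zero-strength region(s) {zero_strength.tolist()}: "
            "cosine similarity row/column set to 0",
            stacklevel=2,
        )
        cos[zero_strength, :] = 0.0
        cos[:, zero_strength] = 0.0
    cos = (cos + cos.T) / 2.0
    np.fill_diagonal(cos, 1.0)
    return PredictorMatrix(
        "CoS", cos, adjusted=False, participant_id=sc.participant_id,
        meta={"exclude_direct": exclude_direct},
    )


def weight_to_length(weights: np.ndarray, rule: str = "inverse") -> np.ndarray:
    """Map non-negative connection weights to traversal lengths.

    ``"inverse"``: L = 1/w (absent edges -> inf).  ``"neglog"``:
    L = -log(w / max w), so the strongest edge has length 0.
    """
    w = np.asarray(weights, dtype=float)
    with np.errstate(divide="ignore"):
        if rule == "inverse":
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        elif rule == "neglog":
            wmax = w.max()
            if wmax <= 0:
                return np.full_like(w, np.inf)
            lengths = np.where(w > 0, -np.log(np.where(w > 0, w, 1.0) / wmax), np.inf)
        else:
            raise ValueError(f"unknown weight-to-length rule {rule!r}")
    np.fill_diagonal(lengths, np.inf)
    return lengths


def _length_graph(lengths: np.ndarray) -> csr_matrix:
    finite = np.isfinite(lengths)
    g = np.where(finite, lengths, 0.0)
    np.fill_diagonal(g, 0.0)
    # csgraph treats explicit zeros as edges only via masked arrays; use csr
    # with only finite off-diagonal entries stored
    n = lengths.shape[0]
    rows, cols = np.nonzero(finite & ~np.eye(n, dtype=bool))
    return csr_matrix((lengths[rows, cols], (rows, cols)), shape=(n, n))


def _apply_inversion(dist: np.ndarray, inversion: str, what: str) -> np.ndarray:
    """Adjust a "cost" matrix so larger means easier; handles unreachable pairs."""
    out = dist.copy()
    off = ~np.eye(out.shape[0], dtype=bool)
    unreachable = ~np.isfinite(out) & off
    if unreachable.any():
        finite_vals = out[np.isfinite(out) & off]
        sentinel = UNREACHABLE_FACTOR * (float(finite_vals.max()) if finite_vals.size else 1.0)
        warnings.warn(
            f"{what}: {int(unreachable.sum())} unreachable pairs assigned "
            f"sentinel cost {sentinel:.3g}",
            stacklevel=3,
        )
        out[unreachable] = sentinel
    if inversion == "negate":
        out = -out
        np.fill_diagonal(out, 0.0)
        return out
    if inversion == "reciprocal":
        with np.errstate(divide="ignore"):
            rec = np.where(out > 0, 1.0 / np.where(out > 0, out, 1.0), np.inf)
        finite_rec = rec[np.isfinite(rec) & off]
        if np.any(~np.isfinite(rec[off])):
            cap = UNREACHABLE_FACTOR * (float(finite_rec.max()) if finite_rec.size else 1.0)
            warnings.warn(
                f"{what}: zero-cost pairs capped at {cap:.3g} under reciprocal "
                "inversion",
                stacklevel=3,
            )
            rec[~np.isfinite(rec)] = cap
        np.fill_diagonal(rec, 0.0)
        return rec
    raise ValueError(f"unknown inversion {inversion!r}")


def path_length_matrix(
    sc: StructuralConnectome,
    rule: str = "inverse",
    inversion: str = "negate",
) -> PredictorMatrix:
    """All-pairs shortest weighted path distances, adjusted so larger = closer.

    Distances come from Dijkstra on the weight-to-length graph; the adjustment
    (negation by default) makes the matrix comparable in direction to the
    other predictors.  Unreachable pairs get a sentinel beyond the largest
    finite distance.
    """
    lengths = weight_to_length(sc.weights, rule)
    dist = dijkstra(_length_graph(lengths), directed=False)
    adj = _apply_inversion(dist, inversion, f"PL[{sc.participant_id}]")
    return PredictorMatrix(
        "PL", adj, adjusted=True, participant_id=sc.participant_id,
        meta={"rule": rule, "inversion": inversion},
    )


def communicability_matrix(sc: StructuralConnectome) -> PredictorMatrix:
    """Strength-normalized weighted communicability exp(D^{-1/2} W D^{-1/2}).

    D is the diagonal matrix of node strengths; rows/columns of zero-strength
    regions are zeroed before exponentiation.  No post-computation adjustment.
    """
    w = sc.weights
    strength = w.sum(axis=0)
    with np.errstate(divide="ignore"):
        d = np.where(strength > 0, 1.0 / np.sqrt(np.where(strength > 0, strength, 1.0)), 0.0)
    m = d[:, None] * w * d[None, :]
    # m symmetric: exponential via eigendecomposition
    vals, vecs = eigh(m)
    expm = (vecs * np.exp(vals)) @ vecs.T
    expm = (expm + expm.T) / 2.0
    return PredictorMatrix("G", expm, adjusted=False, participant_id=sc.participant_id)


def search_information_raw(
    sc: StructuralConnectome, rule: str = "inverse"
) -> np.ndarray:
    """Directed raw search information SI(i -> j), in bits.

    SI(i -> j) = -log2 of the probability that a random walker starting at i
    follows the shortest path to j, where each step u -> v has probability
    w_uv / strength(u).  Shortest paths are taken on the weight-to-length
    graph.  Unreachable pairs are inf; diagonal 0.
    """
    w = sc.weights
    n = w.shape[0]
    strength = w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(
            w > 0, np.log2(np.where(w > 0, w, 1.0)) - np.log2(
                np.where(strength > 0, strength, 1.0)
            )[:, None], -np.inf
        )
    lengths = weight_to_length(w, rule)
    dist, pred = dijkstra(_length_graph(lengths), directed=False,
                          return_predecessors=True)
    si = np.full((n, n), np.inf)
    np.fill_diagonal(si, 0.0)
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        for j in order:
            if j == i or not np.isfinite(dist[i, j]):
                continue
            p = pred[i, j]
            si[i, j] = si[i, p] - logp[p, j]
    return si


def search_information_matrix(
    sc: StructuralConnectome,
    rule: str = "inverse",
    inversion: str = "negate",
) -> PredictorMatrix:
    """Symmetrized, adjusted search information.

    S = (SI(i->j) + SI(j->i)) / 2, then inverted (negated by default) so that
    larger means "more accessible".  Unreachable pairs get a sentinel beyond
    the largest finite SI.  Diagonal 0.
    """
    raw = search_information_raw(sc, rule)
    sym = (raw + raw.T) / 2.0
    adj = _apply_inversion(sym, inversion, f"SI[{sc.participant_id}]")
    return PredictorMatrix(
        "SI", adj, adjusted=True, participant_id=sc.participant_id,
        meta={"rule": rule, "inversion": inversion},
    )


def all_predictors(
    sc: StructuralConnectome, cfg: AnalysisConfig | None = None
) -> list[PredictorMatrix]:
    """The four predictor matrices, in the configured measure order."""
    cfg = cfg or AnalysisConfig()
    builders = {
        "CoS": lambda: cosine_similarity_matrix(sc, cfg.cos_exclude_direct),
        "PL": lambda: path_length_matrix(sc, cfg.weight_to_length, cfg.inversion),
        "G": lambda: communicability_matrix(sc),
        "SI": lambda: search_information_matrix(sc, cfg.weight_to_length, cfg.inversion),
    }
    return [builders[m]() for m in cfg.measure_set]
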