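"""Sequence distances: mismatch profiles, JC69 correction, Scoredist.

The per-query mismatch profile is the reusable core of the replicate
pipeline: a site-by-reference binary matrix ``V`` marking mismatches at
mutually ungapped sites and a companion matrix ``G`` marking the mutually
ungapped sites themselves.  Any row of non-negative site weights ``w``
(bootstrap counts, subsample indicators, or all ones) then yields mismatch
counts ``w @ V`` and valid-site counts ``w @ G`` without touching the
sequences again.

Distances:

* DNA — normalized Hamming distance ``h`` with gaps ignored, corrected by
  the one-parameter JC69 model, ``t = -3/4 * ln(1 - 4h/3)``.  Pairs at or
  beyond the model's saturation point (``h >= 3/4``) are flagged invalid
  rather than capped.
* Amino acids — Scoredist: the BLOSUM62 alignment score, normalized between
  the expected random score and the mean self-score, log-corrected and
  scaled by an empirical coefficient (1.3, the FastTree-2 convention, so
  that distances are commensurable with backbone branch lengths in
  substitutions/site; the original publication's 1.13 is selectable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import Alignment, encode, residue_table

SATURATION = 0.75  # JC69 domain boundary for normalized Hamming distance

#: Distance ceiling for Scoredist pairs whose normalized score is <= 0
#: (the original method's 300-PAM cap, in substitutions/site).
SCOREDIST_MAX = 3.0


# --------------------------------------------------------------------------
# JC69
# --------------------------------------------------------------------------

def jc69_correct(h):
    """JC69-corrected distance ``-3/4 * ln(1 - 4h/3)`` (substitutions/site).

    ``h`` is a normalized Hamming distance (scalar or array).  Values with
    ``h >= 3/4`` are saturated and returned as NaN (the invalid sentinel,
    excluded from placement).  Negative input is an error.
    """
    arr = np.asarray(h, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("normalized Hamming distance must be >= 0")
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr) & (arr < SATURATION)
    out[ok] = -0.75 * np.log1p(-4.0 * arr[ok] / 3.0)
    return float(out) if np.isscalar(h) else out


def jc69_expected_h(t):
    """Expected per-site change probability ``3/4 * (1 - e^(-4t/3))`` under
    JC69; exact inverse of :func:`jc69_correct` on ``[0, 3/4)``."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("distance must be >= 0")
    out = -0.75 * np.expm1(-4.0 * arr / 3.0)
    return float(out) if np.isscalar(t) else out


# --------------------------------------------------------------------------
# mismatch profiles and replicate distances
# --------------------------------------------------------------------------

@dataclass
class MismatchProfile:
    """Per-query binary site×reference matrices.

    ``V[i, j] = 1`` iff site ``i`` is ungapped in both the query and
    reference ``j`` and the characters differ; ``G[i, j] = 1`` iff site
    ``i`` is ungapped in both.  ``V <= G`` elementwise by construction.
    """

    query_id: str
    ref_ids: list
    V: np.ndarray  # (L, n) uint8
    G: np.ndarray  # (L, n) uint8

    @property
    def n_sites(self) -> int:
        return self.V.shape[0]

    @property
    def n_refs(self) -> int:
        return self.V.shape[1]


def build_profile(query_row, backbone: Alignment, query_id: str = "query") -> MismatchProfile:
    """Compare a query against every backbone sequence exactly once.

    ``query_row`` is an aligned sequence (string or uint8 code row) of the
    same length as the backbone alignment.  Ambiguity codes count as gaps.
    """
    q = encode(query_row) if isinstance(query_row, str) else np.asarray(query_row, dtype=np.uint8)
    if q.shape != (backbone.n_sites,):
        raise ValueError(
            f"length mismatch: query has {q.shape[0]} sites, backbone has {backbone.n_sites}"
        )
    qvalid = residue_table(backbone.alphabet)[q]
    both = qvalid[None, :] & backbone.valid_mask  # (n, L)
    mism = (backbone.matrix != q[None, :]) & both
    return MismatchProfile(
        query_id=query_id,
        ref_ids=list(backbone.ids),
        V=mism.T.astype(np.uint8),
        G=both.T.astype(np.uint8),
    )


@dataclass
class DistanceReplicates:
    """Distances of one query to all references, across replicates.

    Row 0 always corresponds to the original (unresampled) alignment; rows
    ``1..B`` are the replicates.  ``corrected`` is NaN where a pair is
    invalid (no mutually ungapped sites, or Hamming distance at/beyond the
    JC69 saturation point); ``valid`` is the matching boolean mask.
    """

    query_id: str
    hamming: np.ndarray      # (B+1, n)
    corrected: np.ndarray    # (B+1, n), NaN = invalid
    valid_sites: np.ndarray  # (B+1, n)

    @property
    def B(self) -> int:
        return self.hamming.shape[0] - 1

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.corrected)


def distances_from_counts(P, Lprime, query_id: str = "query") -> DistanceReplicates:
    """Turn replicate mismatch counts into normalized Hamming and JC69
    distances.

    ``P`` and ``Lprime`` are ``(B+1, n)`` mismatch counts and valid-site
    counts.  Entries with ``Lprime == 0`` or ``h >= 3/4`` are flagged
    invalid (NaN in ``corrected``).
    """
    P = np.asarray(P, dtype=float)
    Lp = np.asarray(Lprime, dtype=float)
    if P.shape != Lp.shape:
        raise ValueError("count matrices have mismatched shapes")
    if np.any(P < 0) or np.any(Lp < 0):
        raise ValueError("negative counts")
    if np.any(P > Lp):
        raise ValueError("mismatch count exceeds valid-site count")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(Lp > 0, P / np.where(Lp > 0, Lp, 1.0), np.nan)
    corrected = jc69_correct(np.where(np.isfinite(h), h, np.inf))
    return DistanceReplicates(query_id=query_id, hamming=h, corrected=corrected, valid_sites=Lp)


# --------------------------------------------------------------------------
# Scoredist (amino acids)
# --------------------------------------------------------------------------

_BLOSUM_CACHE = {}


def _blosum62():
    """BLOSUM62 as (char -> 0..19 lookup table, 20x20 float matrix)."""
    if "tables" not in _BLOSUM_CACHE:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        letters = "ACDEFGHIKLMNPQRSTVWY"
        S = np.empty((20, 20))
        for i, a in enumerate(letters):
            for j, b in enumerate(letters):
                S[i, j] = mat[a, b]
        lut = np.full(256, -1, dtype=np.int16)
        for i, a in enumerate(letters):
            lut[ord(a)] = i
        _BLOSUM_CACHE["tables"] = (lut, S)
    return _BLOSUM_CACHE["tables"]


def scoredist(
    seq_a,
    seq_b,
    coefficient: float = 1.3,
    max_distance: float = SCOREDIST_MAX,
    site_weights=None,
):
    """Scoredist amino-acid distance between two aligned sequences.

    The BLOSUM62 score over mutually ungapped sites is normalized between
    the expected score of randomly paired residues (from the aligned pair's
    own composition) and the mean of the two self-scores; the distance is
    ``-coefficient * ln(normalized)``.  Pairs whose normalized score is
    non-positive get the documented ``max_distance`` sentinel.

    ``site_weights`` (length-L non-negative vector) reweights sites, which
    makes column resampling exact without materializing resampled strings.
    """
    a = encode(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a, dtype=np.uint8)
    b = encode(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ValueError("length mismatch between aligned sequences")
    lut, S = _blosum62()
    ia, ib = lut[a], lut[b]
    mask = (ia >= 0) & (ib >= 0)
    w = np.ones(a.shape[0]) if site_weights is None else np.asarray(site_weights, dtype=float)
    if w.shape != a.shape:
        raise ValueError("site_weights length mismatch")
    w = np.where(mask, w, 0.0)
    l = w.sum()
    if l <= 0:
        raise ValueError("no overlapping ungapped sites")
    ia_m, ib_m, w_m = ia[mask], ib[mask], w[mask]
    sigma = float(np.dot(w_m, S[ia_m, ib_m]))
    sigma_u = float(np.dot(w_m, 0.5 * (S[ia_m, ia_m] + S[ib_m, ib_m])))
    ca = np.bincount(ia_m, weights=w_m, minlength=20)
    cb = np.bincount(ib_m, weights=w_m, minlength=20)
    sigma_r = float(ca @ S @ cb) / l
    num, den = sigma - sigma_r, sigma_u - sigma_r
    if den <= 0 or num <= 0:
        return float(max_distance)
    d = -coefficient * np.log(num / den)
    return float(min(max(d, 0.0), max_distance))


def pairwise_corrected_distances(aln: Alignment, rows=None, site_weights=None) -> np.ndarray:
    """Symmetric matrix of corrected distances among alignment rows
    (JC69 for DNA, Scoredist for amino acids).  NaN marks invalid pairs.

    ``site_weights`` applies a replicate weighting row to all pairs (used
    by branch-length re-estimation on resampled alignments).
    """
    ids = list(aln.ids) if rows is None else list(rows)
    m = len(ids)
    out = np.zeros((m, m))
    if aln.alphabet == "dna":
        mat = np.vstack([aln.row(s) for s in ids])
        valid = residue_table("dna")[mat]
        w = np.ones(aln.n_sites) if site_weights is None else np.asarray(site_weights, dtype=float)
        for i in range(m):
            both = valid[i][None, :] & valid[i + 1:]
            mism = (mat[i + 1:] != mat[i][None, :]) & both
            P = mism @ w
            Lp = both @ w
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.where(Lp > 0, P / np.where(Lp > 0, Lp, 1.0), np.nan)
            d = jc69_correct(np.where(np.isfinite(h), h, np.inf))
            out[i, i + 1:] = d
            out[i + 1:, i] = d
    else:
        for i in range(m):
            for j in range(i + 1, m):
                try:
                    d = scoredist(aln.row(ids[i]), aln.row(ids[j]), site_weights=site_weights)
                except ValueError:
                    d = np.nan
                out[i, j] = out[j, i] = d
    return out
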