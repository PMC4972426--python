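"""Motif representations and the motif-similarity metric.

A motif is a set of equal-length ACGT binding sites, summarized as a 4xL
position frequency matrix (PFM) of per-column base counts and a position
weight matrix (PWM) of per-column log2-odds against a background.

The pairwise score weights cross-likelihoods by column information content:
for an aligned column pair (i, j),

    0.5 * [ IC1(i) * sum_b f2(b, j) * pwm1(b, i)
          + IC2(j) * sum_b f1(b, i) * pwm2(b, j) ]

is summed over the aligned columns of every ungapped offset (overlap >=
``min_overlap``) and both orientations of the second motif, each sum
normalized by the longer motif length so that partial overlaps are
penalized; the maximum is the raw similarity.  Raw scores are normalized by the geometric mean of the
two self-scores so that self-similarity is exactly 1, then clipped to
[-1, 1] and floored at 0.  The score is symmetric and invariant under
reverse-complementing either argument.

This reconstruction is deliberately pluggable: the clustering core consumes
any precomputed edge list, so externally computed similarity files are a
drop-in replacement (see :func:`mocliq.graph.read_edge_list`).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .graph import SimilarityGraph

logger = logging.getLogger(__name__)

__all__ = [
    "Motif", "PFM", "PWM", "MotifError",
    "pfm_from_sites", "column_ic", "pwm_from_pfm",
    "spic_score", "all_pairs_similarity",
    "read_sites_fasta", "read_jaspar_pfm", "load_motifs",
    "write_sites_fasta", "write_pfm",
    "DEFAULT_PSEUDOCOUNT", "DEFAULT_MIN_OVERLAP", "UNIFORM_BACKGROUND",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_MIN_OVERLAP = 4
UNIFORM_BACKGROUND = np.full(4, 0.25)


class MotifError(ValueError):
    """Invalid motif, PFM, or scoring request."""


@dataclass(frozen=True, eq=False)
class PFM:
    """Position frequency matrix: 4xL base counts (rows A, C, G, T)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise MotifError(f"PFM must be 4xL with L >= 1, got shape {counts.shape}")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise MotifError("PFM counts must be finite and nonnegative")
        if np.any(counts.sum(axis=0) <= 0):
            raise MotifError("PFM has an all-zero column")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def reverse_complement(self) -> "PFM":
        # reversing rows maps A<->T and C<->G; reversing columns flips position
        return PFM(self.counts[::-1, ::-1].copy())


@dataclass(frozen=True, eq=False)
class PWM:
    """Per-column log2-odds matrix derived from a PFM."""

    logodds: np.ndarray
    background: np.ndarray
    pseudocount: float


@dataclass(frozen=True, eq=False)
class Motif:
    """A named binding-site set and/or its count matrix.

    ``sites`` is None for motifs loaded from count-matrix files; ``counts``
    is always populated.  ``parent`` optionally records the motif this one
    was derived from (the truth label used in evaluation).
    """

    id: str
    counts: np.ndarray
    sites: tuple[str, ...] | None = None
    parent: str | None = None

    @classmethod
    def from_sites(cls, id: str, sites: Sequence[str], parent: str | None = None) -> "Motif":
        sites = tuple(s.upper() for s in sites)
        if len(sites) < 1:
            raise MotifError(f"motif {id!r}: needs at least one site")
        length = len(sites[0])
        if length < 1:
            raise MotifError(f"motif {id!r}: zero-length sites")
        counts = np.zeros((4, length), dtype=float)
        for s in sites:
            if len(s) != length:
                raise MotifError(
                    f"motif {id!r}: ragged site lengths ({len(s)} != {length})"
                )
            for pos, base in enumerate(s):
                try:
                    counts[_BASE_INDEX[base], pos] += 1
                except KeyError:
                    raise MotifError(
                        f"motif {id!r}: site contains non-ACGT symbol {base!r}"
                    ) from None
        return cls(id=id, counts=counts, sites=sites, parent=parent)

    @classmethod
    def from_counts(cls, id: str, counts: np.ndarray, parent: str | None = None) -> "Motif":
        return cls(id=id, counts=PFM(counts).counts, sites=None, parent=parent)

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", PFM(self.counts).counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sites(self) -> int:
        return int(round(self.counts[:, 0].sum()))

    def pfm(self) -> PFM:
        return PFM(self.counts)

    def reverse_complement(self) -> "Motif":
        rc_sites = None
        if self.sites is not None:
            table = str.maketrans("ACGT", "TGCA")
            rc_sites = tuple(s.translate(table)[::-1] for s in self.sites)
        return Motif(id=self.id, counts=self.counts[::-1, ::-1].copy(),
                     sites=rc_sites, parent=self.parent)


def pfm_from_sites(m: Motif) -> PFM:
    """Count matrix of a site-based motif (column sums equal n_sites)."""
    if m.sites is None:
        return m.pfm()
    return Motif.from_sites(m.id, m.sites).pfm()


def _smoothed_frequencies(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    col_sums = counts.sum(axis=0)
    return (counts + pseudocount) / (col_sums + 4.0 * pseudocount)


def column_ic(pfm: PFM | np.ndarray, pseudocount: float = 0.0) -> np.ndarray:
    """Per-column information content in bits: 2 + sum_b f_b log2 f_b.

    Frequencies are pseudocount-smoothed; 0*log(0) is taken as 0.  Fully
    conserved columns give 2 bits, uniform columns give 0.
    """
    if pseudocount < 0:
        raise MotifError(f"pseudocount must be >= 0, got {pseudocount}")
    counts = pfm.counts if isinstance(pfm, PFM) else PFM(pfm).counts
    f = _smoothed_frequencies(counts, pseudocount)
    plogp = np.zeros_like(f)
    nz = f > 0
    plogp[nz] = f[nz] * np.log2(f[nz])
    return 2.0 + plogp.sum(axis=0)


def pwm_from_pfm(pfm: PFM | np.ndarray, background: np.ndarray | None = None,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PWM:
    """log2-odds matrix from pseudocount-smoothed column frequencies."""
    counts = pfm.counts if isinstance(pfm, PFM) else PFM(pfm).counts
    bg = _validate_background(background)
    f = _smoothed_frequencies(counts, pseudocount)
    with np.errstate(divide="ignore"):
        logodds = np.log2(f / bg[:, None])
    return PWM(logodds=logodds, background=bg, pseudocount=pseudocount)


def _validate_background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return UNIFORM_BACKGROUND.copy()
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise MotifError("background must be 4 positive probabilities summing to 1")
    return bg


# -- scoring -----------------------------------------------------------


@dataclass(frozen=True, eq=False)
class _Profile:
    """Precomputed scoring arrays for one motif orientation."""

    freqs: np.ndarray     # 4xL smoothed frequencies
    logodds: np.ndarray   # 4xL
    ic: np.ndarray        # L


def _make_profile(counts: np.ndarray, background: np.ndarray, pseudocount: float) -> _Profile:
    f = _smoothed_frequencies(counts, pseudocount)
    with np.errstate(divide="ignore"):
        logodds = np.log2(f / background[:, None])
    plogp = np.zeros_like(f)
    nz = f > 0
    plogp[nz] = f[nz] * np.log2(f[nz])
    return _Profile(freqs=f, logodds=logodds, ic=2.0 + plogp.sum(axis=0))


def _raw(p1: _Profile, p2: _Profile, min_overlap: int) -> float:
    """Best per-offset column-score sum of p2 against p1.

    Each ungapped offset's aligned-column sum is normalized by the longer
    motif length (not the overlap), so a short high-scoring overlap cannot
    outrank a full-length alignment.
    """
    cross = 0.5 * (
        p1.ic[:, None] * (p1.logodds.T @ p2.freqs)
        + p2.ic[None, :] * (p1.freqs.T @ p2.logodds)
    )
    l1, l2 = cross.shape
    denom = float(max(l1, l2))
    best = -math.inf
    for offset in range(-(l1 - min_overlap), l2 - min_overlap + 1):
        diag = np.diagonal(cross, offset=offset)
        best = max(best, float(diag.sum()) / denom)
    return best


def _self_raw(fwd: _Profile, rc: _Profile, min_overlap: int) -> float:
    return max(_raw(fwd, fwd, min_overlap), _raw(fwd, rc, min_overlap))


def _orientations(m: Motif, background: np.ndarray, pseudocount: float) -> tuple[_Profile, _Profile]:
    fwd = _make_profile(m.counts, background, pseudocount)
    rc = _make_profile(m.counts[::-1, ::-1], background, pseudocount)
    return fwd, rc


def spic_score(m1: Motif, m2: Motif, min_overlap: int = DEFAULT_MIN_OVERLAP,
               background: np.ndarray | None = None,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """IC-weighted cross-likelihood similarity in [0, 1].

    Maximizes over ungapped offsets (overlap >= ``min_overlap``) and both
    orientations of ``m2``, then normalizes by the geometric mean of the two
    self-scores.  Returns 0 when either self-score is non-positive (fully
    uninformative motif).
    """
    if min_overlap < 1:
        raise MotifError(f"min_overlap must be >= 1, got {min_overlap}")
    if min_overlap > min(m1.length, m2.length):
        raise MotifError(
            f"min_overlap={min_overlap} exceeds the shorter motif length "
            f"({min(m1.length, m2.length)})"
        )
    bg = _validate_background(background)
    p1, p1rc = _orientations(m1, bg, pseudocount)
    p2, p2rc = _orientations(m2, bg, pseudocount)
    raw12 = max(_raw(p1, p2, min_overlap), _raw(p1, p2rc, min_overlap))
    raw11 = _self_raw(p1, p1rc, min_overlap)
    raw22 = _self_raw(p2, p2rc, min_overlap)
    return _normalize(raw12, raw11, raw22)


def _normalize(raw12: float, raw11: float, raw22: float) -> float:
    if raw11 <= 0.0 or raw22 <= 0.0:
        return 0.0
    score = raw12 / math.sqrt(raw11 * raw22)
    score = min(1.0, max(-1.0, score))
    return max(0.0, score)


def all_pairs_similarity(motifs: Sequence[Motif], gamma: float,
                         workers: int = 1,
                         min_overlap: int = DEFAULT_MIN_OVERLAP,
                         background: np.ndarray | None = None,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT) -> SimilarityGraph:
    """Similarity graph over a motif collection at cutoff ``gamma``.

    Every motif id becomes a node; an edge (i, j) is present iff the pairwise
    score is >= gamma.  Deterministic for any ``workers`` value.
    """
    if len(motifs) < 2:
        raise MotifError("need at least 2 motifs")
    if workers < 1:
        raise MotifError(f"workers must be >= 1, got {workers}")
    ids = [m.id for m in motifs]
    if len(set(ids)) != len(ids):
        raise MotifError("duplicate motif ids")
    bg = _validate_background(background)

    profiles = [_orientations(m, bg, pseudocount) for m in motifs]
    self_raws = [_self_raw(fwd, rc, min_overlap) for fwd, rc in profiles]
    for m in motifs:
        if min_overlap > m.length:
            raise MotifError(
                f"min_overlap={min_overlap} exceeds length of motif {m.id!r}"
            )

    g = SimilarityGraph(gamma=gamma)
    for m in motifs:
        g.add_node(m.id)
    n = len(motifs)
    for i in range(n):
        p1, _ = profiles[i]
        for j in range(i + 1, n):
            p2, p2rc = profiles[j]
            raw12 = max(_raw(p1, p2, min_overlap), _raw(p1, p2rc, min_overlap))
            score = _normalize(raw12, self_raws[i], self_raws[j])
            if score >= gamma:
                g.add_edge(ids[i], ids[j], score)
    return g


# -- I/O ---------------------------------------------------------------


def read_sites_fasta(path: str | Path, id: str | None = None) -> Motif:
    """Read a binding-site FASTA: one record per site.

    Lowercase letters are flanking context and are stripped; only the
    uppercase core is kept.  Sites containing non-ACGT symbols in the core
    are dropped with a warning.
    """
    path = Path(path)
    motif_id = id if id is not None else path.stem
    sites: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        core = "".join(ch for ch in str(record.seq) if ch.isupper())
        if not core:
            logger.warning("%s: record %s has no uppercase core; dropped", path, record.id)
            continue
        if any(ch not in _BASE_INDEX for ch in core):
            logger.warning("%s: record %s contains non-ACGT core symbols; dropped", path, record.id)
            continue
        sites.append(core)
    if not sites:
        raise MotifError(f"{path}: no usable sites")
    return Motif.from_sites(motif_id, sites)


_JASPAR_ROW = re.compile(r"^\s*([ACGTacgt])\s*\[([^\]]*)\]")


def read_jaspar_pfm(path: str | Path, id: str | None = None) -> Motif:
    """Read a count-matrix file: 4 rows (A, C, G, T) of counts.

    Accepts an optional ``>id`` header line, plain whitespace-separated rows,
    and the bracketed dialect ``A [ 3 5 ... ]``.
    """
    path = Path(path)
    motif_id = id
    rows: dict[str, list[float]] = {}
    plain_rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            text = line.strip()
            if not text:
                continue
            if text.startswith(">"):
                if motif_id is None:
                    motif_id = text[1:].split()[0] if len(text) > 1 else None
                continue
            m = _JASPAR_ROW.match(text)
            if m:
                rows[m.group(1).upper()] = [float(x) for x in m.group(2).split()]
            else:
                try:
                    plain_rows.append([float(x) for x in text.split()])
                except ValueError:
                    raise MotifError(f"{path}: unparseable matrix line {text!r}") from None
    if rows:
        if set(rows) != set(BASES):
            raise MotifError(f"{path}: expected rows A, C, G, T; got {sorted(rows)}")
        counts = np.array([rows[b] for b in BASES], dtype=float)
    elif len(plain_rows) == 4:
        counts = np.array(plain_rows, dtype=float)
    else:
        raise MotifError(f"{path}: expected 4 count rows, got {len(plain_rows)}")
    if motif_id is None:
        motif_id = path.stem
    return Motif.from_counts(motif_id, counts)


def load_motifs(paths: Iterable[str | Path]) -> list[Motif]:
    """Load a motif per file, dispatching on suffix (.fa/.fasta/.sites vs matrix)."""
    motifs: list[Motif] = []
    for p in paths:
        p = Path(p)
        if p.suffix.lower() in (".fa", ".fasta", ".sites"):
            motifs.append(read_sites_fasta(p))
        else:
            motifs.append(read_jaspar_pfm(p))
    return motifs


def write_sites_fasta(m: Motif, path: str | Path) -> None:
    if m.sites is None:
        raise MotifError(f"motif {m.id!r} has no sites to write")
    with Path(path).open("w") as fh:
        for i, s in enumerate(m.sites, start=1):
            fh.write(f">{m.id}_site{i}\n{s}\n")


def write_pfm(m: Motif, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f">{m.id}\n")
        for row_idx, base in enumerate(BASES):
            values = " ".join(f"{v:g}" for v in m.counts[row_idx])
            fh.write(f"{base} [ {values} ]\n")
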