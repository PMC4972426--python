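"""Clustering quality measures: ARI, correspondence fractions, recovery curves."""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EvaluationError", "ContingencyTable", "contingency", "adjusted_rand_index",
    "ari", "CorrespondenceStats", "correspondence_stats",
    "RecoveryCurve", "recovery_curve",
    "read_labels_tsv", "write_labels_tsv",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True, eq=False)
class ContingencyTable:
    """n_ij counts of objects shared by truth class i and predicted cluster j."""

    counts: np.ndarray
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise EvaluationError("contingency counts must be a 2-D array")
        if np.any(counts < 0):
            raise EvaluationError("contingency counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contingency(truth: Mapping[str, object], pred: Mapping[str, object],
                drop_missing: bool = False) -> ContingencyTable:
    """Cross-tabulate two label assignments over the same node universe.

    With ``drop_missing`` the table is built on the intersection of the two
    key sets; otherwise differing universes raise, naming offending ids.
    """
    t_keys, p_keys = set(truth), set(pred)
    if t_keys != p_keys:
        if not drop_missing:
            missing = sorted((t_keys ^ p_keys))[:10]
            raise EvaluationError(
                f"node universes differ ({len(t_keys ^ p_keys)} mismatched ids, "
                f"e.g. {missing}); pass drop_missing=True to intersect"
            )
        common = t_keys & p_keys
    else:
        common = t_keys
    row_labels = tuple(sorted({truth[k] for k in common}, key=str))
    col_labels = tuple(sorted({pred[k] for k in common}, key=str))
    r_index = {lab: i for i, lab in enumerate(row_labels)}
    c_index = {lab: j for j, lab in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for k in common:
        counts[r_index[truth[k]], c_index[pred[k]]] += 1
    return ContingencyTable(counts=counts, row_labels=row_labels, col_labels=col_labels)


def adjusted_rand_index(t: ContingencyTable) -> float:
    """Chance-corrected pair-counting agreement from a contingency table.

    ARI = [S_ij - S_i*S_j/C(N,2)] / [(S_i + S_j)/2 - S_i*S_j/C(N,2)]
    where S_ij = sum C(n_ij, 2), S_i = sum C(n_i., 2), S_j = sum C(n_.j, 2).
    When the denominator vanishes (both partitions trivial) the value is 1 if
    the numerator is also 0, else 0.
    """
    n_total = t.total
    if n_total < 2:
        raise EvaluationError(f"need at least 2 objects, got {n_total}")
    sum_ij = sum(comb(int(v), 2) for v in t.counts.flat)
    sum_i = sum(comb(int(v), 2) for v in t.row_sums)
    sum_j = sum(comb(int(v), 2) for v in t.col_sums)
    expected = sum_i * sum_j / comb(n_total, 2)
    numerator = sum_ij - expected
    denominator = 0.5 * (sum_i + sum_j) - expected
    if denominator == 0:
        return 1.0 if numerator == 0 else 0.0
    return numerator / denominator


def ari(truth: Mapping[str, object], pred: Mapping[str, object],
        drop_missing: bool = False) -> float:
    return adjusted_rand_index(contingency(truth, pred, drop_missing=drop_missing))


@dataclass(frozen=True)
class CorrespondenceStats:
    """Fractions quantifying 1:1 correspondence between clusters and labels."""

    single_label_clusters: float   # clusters whose members carry one truth label
    single_cluster_labels: float   # labels whose members sit in one cluster
    n_clusters: int
    n_labels: int


def correspondence_stats(truth: Mapping[str, object],
                         clusters: Sequence[Iterable[str]]) -> CorrespondenceStats:
    """Per-cluster label purity and per-label cluster spread fractions."""
    cluster_sets = [set(c) for c in clusters]
    if not cluster_sets:
        raise EvaluationError("empty cluster list")
    clustered = set().union(*cluster_sets)
    missing = sorted(x for x in clustered if x not in truth)
    if missing:
        raise EvaluationError(f"no truth label for clustered nodes, e.g. {missing[:10]}")
    single_label = sum(1 for c in cluster_sets if len({truth[x] for x in c}) == 1)

    label_clusters: dict[object, set[int]] = {}
    for idx, c in enumerate(cluster_sets):
        for x in c:
            label_clusters.setdefault(truth[x], set()).add(idx)
    single_cluster = sum(1 for v in label_clusters.values() if len(v) == 1)
    return CorrespondenceStats(
        single_label_clusters=single_label / len(cluster_sets),
        single_cluster_labels=single_cluster / len(label_clusters),
        n_clusters=len(cluster_sets),
        n_labels=len(label_clusters),
    )


@dataclass(frozen=True)
class RecoveryCurve:
    """Cumulative counts over ranked clusters; both series are non-decreasing."""

    known_cumulative: tuple[int, ...]
    member_cumulative: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.known_cumulative)


def recovery_curve(clusters: Sequence[Iterable[str]], known: Iterable[str]) -> RecoveryCurve:
    """Per rank r: distinct known items and total members seen in clusters 1..r."""
    known_set = set(known)
    seen_known: set[str] = set()
    known_cum: list[int] = []
    member_cum: list[int] = []
    members_so_far = 0
    for c in clusters:
        members = set(c)
        members_so_far += len(members)
        seen_known |= members & known_set
        known_cum.append(len(seen_known))
        member_cum.append(members_so_far)
    return RecoveryCurve(known_cumulative=tuple(known_cum),
                         member_cumulative=tuple(member_cum))


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """2-column TSV: node id, label."""
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split("\t")
            if len(parts) < 2:
                raise EvaluationError(f"{path}:{lineno}: expected 2 tab-separated columns")
            out[parts[0]] = parts[1]
    return out


def write_labels_tsv(labels: Mapping[str, object], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for node in sorted(labels):
            fh.write(f"{node}\t{labels[node]}\n")
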