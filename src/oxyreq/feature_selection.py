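"""Selection of class-associated domains and construction of likelihood tables.

A domain is associated with a task class when it is present in at least 65%
of that class's genomes, its in-class presence frequency exceeds the pooled
frequency of the remaining classes, and a two-tailed two-sample t-test on the
0/1 indicators gives p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from oxyreq.core_io import ClassScheme, LikelihoodTable, PresenceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds for class-associated domain selection."""

    presence_threshold: float = 0.65
    alpha: float = 0.05
    welch: bool = False  # unequal-variance t-test instead of pooled-variance

    def __post_init__(self) -> None:
        if not 0 < self.presence_threshold <= 1:
            raise ValueError("presence_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


class EmptyClassError(ValueError):
    """A task class has no (or too few) member genomes."""


def _task_class_indicators(
    matrix: PresenceMatrix, labels: Mapping[str, str], scheme: ClassScheme
) -> np.ndarray:
    """Boolean membership matrix, shape (n_task_classes, n_genomes).

    Genomes whose base label is excluded by the scheme get all-False columns.
    """
    missing = [g for g in matrix.genome_ids if g not in labels]
    if missing:
        raise KeyError(f"genomes without labels: {missing[:5]}")
    member = np.zeros((len(scheme.classes), matrix.n_genomes), dtype=bool)
    for i, g in enumerate(matrix.genome_ids):
        task = scheme.task_label(labels[g])
        if task is not None:
            member[scheme.index(task), i] = True
    return member


def class_frequencies(
    matrix: PresenceMatrix, labels: Mapping[str, str], scheme: ClassScheme
) -> np.ndarray:
    """Per-domain presence frequency in each task class.

    Returns an array of shape (n_domains, n_task_classes) in scheme order.
    """
    member = _task_class_indicators(matrix, labels, scheme)
    n_per_class = member.sum(axis=1)
    for cls_name, n in zip(scheme.classes, n_per_class):
        if n == 0:
            raise EmptyClassError(f"task class {cls_name!r} has no member genomes")
    counts = member.astype(np.int64) @ matrix.values.astype(np.int64)  # (K, D)
    return (counts / n_per_class[:, None]).T


def _t_from_counts(
    count_x: np.ndarray,
    n_x: int,
    count_y: np.ndarray,
    n_y: int,
    welch: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sample t-test on 0/1 samples summarized by counts.

    Equivalent to running the classical t-test on the explicit indicator
    vectors: sample variances use the n-1 denominator; pooled-variance
    Student form by default, Welch optionally. Zero-variance degenerate
    case: p = 1 when the proportions are equal, p = 0 otherwise.
    """
    count_x = np.asarray(count_x, dtype=float)
    count_y = np.asarray(count_y, dtype=float)
    if n_x < 2 or n_y < 2:
        raise ValueError("each group needs at least 2 samples (variance undefined)")
    p_x = count_x / n_x
    p_y = count_y / n_y
    # sum of squared deviations of a 0/1 sample with c ones: c - c^2/n
    ss_x = count_x - count_x**2 / n_x
    ss_y = count_y - count_y**2 / n_y
    if welch:
        var_x = ss_x / (n_x - 1)
        var_y = ss_y / (n_y - 1)
        se2 = var_x / n_x + var_y / n_y
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (var_x / n_x) ** 2 / (n_x - 1) + (var_y / n_y) ** 2 / (n_y - 1)
            )
    else:
        sp2 = (ss_x + ss_y) / (n_x + n_y - 2)
        se2 = sp2 * (1.0 / n_x + 1.0 / n_y)
        df = np.full_like(se2, float(n_x + n_y - 2))
    diff = p_x - p_y
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            t_deg = np.where(diff == 0, 0.0, np.sign(diff) * np.inf)
        t = np.where(degenerate, t_deg, t)
        p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def binary_t_test(
    count_x: int, n_x: int, count_y: int, n_y: int, welch: bool = False
) -> tuple[float, float]:
    """Two-tailed two-sample t-test between two groups of 0/1 indicators.

    ``count_x`` of ``n_x`` genomes in group X carry the domain, likewise for
    Y. Returns (t statistic, two-tailed p-value).
    """
    for count, n in ((count_x, n_x), (count_y, n_y)):
        if not 0 <= count <= n:
            raise ValueError(f"count {count} outside [0, {n}]")
    t, p = _t_from_counts(
        np.array([count_x]), n_x, np.array([count_y]), n_y, welch=welch
    )
    return float(t[0]), float(p[0])


def select_class_associated_domains(
    matrix: PresenceMatrix,
    labels: Mapping[str, str],
    scheme: ClassScheme,
    params: SelectionParams = SelectionParams(),
) -> LikelihoodTable:
    """Build the likelihood table of class-associated domains.

    For every task class C, each domain is tested against the pooled
    remaining classes; a domain is selected for C when its in-class
    frequency passes the presence threshold, strictly exceeds the pooled
    rest frequency, and the t-test p-value is below alpha. If a domain
    qualifies for several classes it is assigned to the class where its
    frequency is highest (smallest p as tiebreak).
    """
    member = _task_class_indicators(matrix, labels, scheme)
    n_per_class = member.sum(axis=1)
    for cls_name, n in zip(scheme.classes, n_per_class):
        if n < 2:
            raise EmptyClassError(
                f"task class {cls_name!r} has {n} member genome(s); need >= 2"
            )
    values = matrix.values.astype(np.int64)
    counts = member.astype(np.int64) @ values  # (K, D)
    freqs = counts / n_per_class[:, None]

    n_classes, n_domains = counts.shape
    qualifies = np.zeros((n_classes, n_domains), dtype=bool)
    t_all = np.zeros((n_classes, n_domains))
    p_all = np.ones((n_classes, n_domains))
    for k in range(n_classes):
        n_in = int(n_per_class[k])
        n_rest = int(n_per_class.sum() - n_in)
        if n_rest < 2:
            raise EmptyClassError(
                f"pooled rest of class {scheme.classes[k]!r} has {n_rest} genome(s)"
            )
        rest_counts = counts.sum(axis=0) - counts[k]
        t, p = _t_from_counts(counts[k], n_in, rest_counts, n_rest, welch=params.welch)
        t_all[k] = t
        p_all[k] = p
        freq_rest = rest_counts / n_rest
        qualifies[k] = (
            (freqs[k] >= params.presence_threshold)
            & (freqs[k] > freq_rest)
            & (p < params.alpha)
        )

    selected = np.where(qualifies.any(axis=0))[0]
    if selected.size == 0:
        logger.warning("no class-associated domains selected")
        return LikelihoodTable.empty(scheme.classes)

    domain_ids: list[str] = []
    assoc: list[str] = []
    t_sel: list[float] = []
    p_sel: list[float] = []
    for j in selected:
        candidates = np.where(qualifies[:, j])[0]
        if len(candidates) == 1:
            k = int(candidates[0])
        else:  # rare: pick the class with highest in-class frequency, then lowest p
            order = sorted(candidates, key=lambda k: (-freqs[k, j], p_all[k, j]))
            k = int(order[0])
        domain_ids.append(matrix.domain_ids[j])
        assoc.append(scheme.classes[k])
        t_sel.append(float(t_all[k, j]))
        p_sel.append(float(p_all[k, j]))

    return LikelihoodTable(
        classes=scheme.classes,
        domain_ids=domain_ids,
        likelihoods=freqs[:, selected].T,
        associated_class=assoc,
        t_stats=np.array(t_sel),
        p_values=np.array(p_sel),
    )
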