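"""Shared domain types and readers/writers for the on-disk formats.

Formats (all plain TSV):

* presence matrix -- header ``genome_id<TAB>PF...<TAB>...``; one row per
  genome, cells are 0/1.
* label map -- two columns ``genome_id<TAB>class`` with class in
  {aerobe, anaerobe, facultative}.
* likelihood table -- ``domain<TAB>associated_class`` followed by one
  likelihood column per task class (column order = scheme order) and
  optional ``t``/``p`` selection-statistic columns.
* hmmscan tabular output (tblout or domtblout): '#' comment lines,
  whitespace-delimited fields, Pfam accession in the second field.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical base classes, in canonical order.
BASE_CLASSES: tuple[str, ...] = ("aerobe", "anaerobe", "facultative")

_PFAM_ACC_RE = re.compile(r"^(PF\w*?\d+)(?:\.\d+)?$")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class DuplicateIdentifierError(FormatError):
    """Raised when a genome or domain identifier occurs twice."""


# ---------------------------------------------------------------------------
# Class schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassScheme:
    """A prediction task: an ordered set of task classes plus the rule
    mapping base labels onto them.

    Base labels absent from ``merge`` are excluded from the task (used by
    the aerobe-vs-facultative step and the aerobe/anaerobe-only mode).
    """

    classes: tuple[str, ...]
    merge: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a class scheme needs at least 2 task classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate task class names")
        bad = set(self.merge.values()) - set(self.classes)
        if bad:
            raise ValueError(f"merge rule targets unknown classes: {sorted(bad)}")

    def task_label(self, base_label: str) -> str | None:
        """Task class for a base label, or None if excluded from this task."""
        return self.merge.get(base_label)

    def index(self, task_class: str) -> int:
        return self.classes.index(task_class)


#: Flat three-class task.
ONE_STEP_SCHEME = ClassScheme(
    classes=BASE_CLASSES,
    merge={c: c for c in BASE_CLASSES},
)

#: Step 1 of the nested dichotomy: respiration-capable vs. anaerobe.
STEP1_SCHEME = ClassScheme(
    classes=("respiring", "anaerobe"),
    merge={"aerobe": "respiring", "facultative": "respiring", "anaerobe": "anaerobe"},
)

#: Step 2: aerobe vs. facultative, anaerobes excluded from training.
STEP2_SCHEME = ClassScheme(
    classes=("aerobe", "facultative"),
    merge={"aerobe": "aerobe", "facultative": "facultative"},
)

#: Two-class comparison mode: facultative genomes dropped entirely.
AA_ONLY_SCHEME = ClassScheme(
    classes=("aerobe", "anaerobe"),
    merge={"aerobe": "aerobe", "anaerobe": "anaerobe"},
)


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Binary genome x Pfam-domain matrix (genomes in rows)."""

    genome_ids: list[str]
    domain_ids: list[str]
    values: np.ndarray  # shape (n_genomes, n_domains), dtype uint8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.genome_ids), len(self.domain_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.genome_ids)} genomes x {len(self.domain_ids)} domains"
            )
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise DuplicateIdentifierError("duplicate genome identifiers")
        if len(set(self.domain_ids)) != len(self.domain_ids):
            raise DuplicateIdentifierError("duplicate domain identifiers")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence matrix values must be 0 or 1")
        zero = [g for g, s in zip(self.genome_ids, self.values.sum(axis=1)) if s == 0]
        if zero:
            logger.warning(
                "%d genome(s) have no present domains: %s",
                len(zero),
                ", ".join(zero[:5]) + ("..." if len(zero) > 5 else ""),
            )
        self._genome_index = {g: i for i, g in enumerate(self.genome_ids)}

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_domains(self) -> int:
        return len(self.domain_ids)

    def row(self, genome_id: str) -> np.ndarray:
        return self.values[self._genome_index[genome_id]]

    def present_domains(self, genome_id: str) -> set[str]:
        r = self.row(genome_id)
        return {d for d, v in zip(self.domain_ids, r) if v}

    def drop_genomes(self, genome_ids: Iterable[str]) -> "PresenceMatrix":
        drop = set(genome_ids)
        keep = [i for i, g in enumerate(self.genome_ids) if g not in drop]
        return PresenceMatrix(
            [self.genome_ids[i] for i in keep],
            list(self.domain_ids),
            self.values[keep],
        )

    @classmethod
    def from_presence_sets(
        cls,
        presence: Mapping[str, set[str]],
        domain_ids: Sequence[str] | None = None,
    ) -> "PresenceMatrix":
        """Build a matrix from per-genome sets of present domains.

        The domain universe defaults to the sorted union of all sets.
        """
        genomes = list(presence)
        if domain_ids is None:
            domain_ids = sorted(set().union(*presence.values())) if presence else []
        domain_ids = list(domain_ids)
        idx = {d: j for j, d in enumerate(domain_ids)}
        values = np.zeros((len(genomes), len(domain_ids)), dtype=np.uint8)
        for i, g in enumerate(genomes):
            for d in presence[g]:
                if d in idx:
                    values[i, idx[d]] = 1
        return cls(genomes, domain_ids, values)


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    """Read a presence/absence matrix TSV (header row, then one row per genome)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        domain_ids = cols[1:]
        genome_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            genome = parts[0]
            row: list[int] = []
            for dom, cell in zip(domain_ids, parts[1:]):
                if cell == "0":
                    row.append(0)
                elif cell == "1":
                    row.append(1)
                else:
                    raise FormatError(
                        f"{path}:{lineno}: non-binary value {cell!r} "
                        f"for genome {genome!r}, domain {dom!r}"
                    )
            genome_ids.append(genome)
            rows.append(row)
    values = (
        np.array(rows, dtype=np.uint8)
        if rows
        else np.zeros((0, len(domain_ids)), dtype=np.uint8)
    )
    return PresenceMatrix(genome_ids, domain_ids, values)


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("genome_id\t" + "\t".join(matrix.domain_ids) + "\n")
        for g, row in zip(matrix.genome_ids, matrix.values):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


def read_labels(path: str | Path, valid: Sequence[str] = BASE_CLASSES) -> dict[str, str]:
    """Read a two-column genome_id -> class TSV."""
    path = Path(path)
    labels: dict[str, str] = {}
    valid_set = set(valid)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            genome, cls = parts
            if genome == "genome_id":  # optional header
                continue
            if cls not in valid_set:
                raise FormatError(
                    f"{path}:{lineno}: unknown class {cls!r} "
                    f"(expected one of {sorted(valid_set)})"
                )
            if genome in labels:
                raise DuplicateIdentifierError(f"{path}:{lineno}: duplicate genome {genome!r}")
            labels[genome] = cls
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("genome_id\tclass\n")
        for g, c in labels.items():
            fh.write(f"{g}\t{c}\n")


# ---------------------------------------------------------------------------
# hmmscan output
# ---------------------------------------------------------------------------


def parse_hmmscan_table(path: str | Path) -> set[str]:
    """Extract the set of Pfam accessions hit in an hmmscan tblout/domtblout file.

    Accession version suffixes are stripped (``PF00001.21`` -> ``PF00001``);
    hit multiplicity is discarded. Lines whose accession field cannot be
    parsed are skipped with a warning.
    """
    path = Path(path)
    accessions: set[str] = set()
    n_data = 0
    n_skipped = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            n_data += 1
            fields = line.split()
            acc = None
            # tblout and domtblout both carry the target accession in field 2;
            # fall back to the target name when the accession column is '-'.
            for candidate in fields[1:2] + fields[0:1]:
                m = _PFAM_ACC_RE.match(candidate)
                if m:
                    acc = m.group(1)
                    break
            if acc is None:
                n_skipped += 1
                continue
            accessions.add(acc)
    if n_data == 0:
        logger.warning("%s: no data lines found", path)
    if n_skipped:
        logger.warning("%s: skipped %d line(s) with unparsable accession", path, n_skipped)
    return accessions


# ---------------------------------------------------------------------------
# Likelihood table
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodTable:
    """Selected class-associated domains with p(domain present | class).

    ``likelihoods[i, j]`` is the presence frequency of ``domain_ids[i]`` in
    task class ``classes[j]``; ``associated_class[i]`` is the single class in
    which the domain was found overrepresented. ``t_stats``/``p_values`` hold
    the selection statistics when available.
    """

    classes: tuple[str, ...]
    domain_ids: list[str]
    likelihoods: np.ndarray  # (n_domains, n_classes)
    associated_class: list[str]
    t_stats: np.ndarray | None = None
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=float).reshape(
            len(self.domain_ids), len(self.classes)
        )
        if len(self.associated_class) != len(self.domain_ids):
            raise ValueError("associated_class length mismatch")
        if self.likelihoods.size and (
            (self.likelihoods < 0).any() or (self.likelihoods > 1).any()
        ):
            raise ValueError("likelihoods must lie in [0, 1]")
        unknown = set(self.associated_class) - set(self.classes)
        if unknown:
            raise ValueError(f"associated classes not in scheme: {sorted(unknown)}")
        if self.t_stats is not None:
            self.t_stats = np.asarray(self.t_stats, dtype=float)
        if self.p_values is not None:
            self.p_values = np.asarray(self.p_values, dtype=float)

    @property
    def n_domains(self) -> int:
        return len(self.domain_ids)

    def is_empty(self) -> bool:
        return self.n_domains == 0

    @classmethod
    def empty(cls, classes: Sequence[str]) -> "LikelihoodTable":
        return cls(
            tuple(classes),
            [],
            np.zeros((0, len(classes))),
            [],
            np.zeros(0),
            np.zeros(0),
        )


def read_likelihood_table(path: str | Path) -> LikelihoodTable:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[:2] != ["domain", "associated_class"]:
            raise FormatError(
                f"{path}: header must start with 'domain\\tassociated_class', got {cols[:2]}"
            )
        rest = cols[2:]
        has_stats = rest[-2:] == ["t", "p"]
        classes = tuple(rest[:-2] if has_stats else rest)
        if len(classes) < 2:
            raise FormatError(f"{path}: need at least 2 likelihood columns, got {classes}")
        domains: list[str] = []
        assoc: list[str] = []
        lik_rows: list[list[float]] = []
        t_vals: list[float] = []
        p_vals: list[float] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            domains.append(parts[0])
            if parts[1] not in classes:
                raise FormatError(
                    f"{path}:{lineno}: associated class {parts[1]!r} not among {classes}"
                )
            assoc.append(parts[1])
            lik = [float(x) for x in parts[2 : 2 + len(classes)]]
            for cls_name, value in zip(classes, lik):
                if not 0.0 <= value <= 1.0:
                    raise FormatError(
                        f"{path}:{lineno}: likelihood {value} for class "
                        f"{cls_name!r} outside [0, 1]"
                    )
            lik_rows.append(lik)
            if has_stats:
                t_vals.append(float(parts[-2]))
                p_vals.append(float(parts[-1]))
    lik = np.array(lik_rows, dtype=float) if lik_rows else np.zeros((0, len(classes)))
    return LikelihoodTable(
        classes,
        domains,
        lik,
        assoc,
        np.array(t_vals) if has_stats else None,
        np.array(p_vals) if has_stats else None,
    )


def write_likelihood_table(table: LikelihoodTable, path: str | Path) -> None:
    path = Path(path)
    has_stats = table.t_stats is not None and table.p_values is not None
    with path.open("w") as fh:
        header = ["domain", "associated_class", *table.classes]
        if has_stats:
            header += ["t", "p"]
        fh.write("\t".join(header) + "\n")
        for i, dom in enumerate(table.domain_ids):
            row = [dom, table.associated_class[i]]
            row += [repr(float(v)) for v in table.likelihoods[i]]
            if has_stats:
                row += [repr(float(table.t_stats[i])), repr(float(table.p_values[i]))]
            fh.write("\t".join(row) + "\n")
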