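"""Synthetic labeled presence/absence matrices with planted class structure.

Each class gets a block of associated domains present with probability
``p_in`` inside the class and ``p_out`` outside it, on top of uninformative
background domains shared by all classes at ``p_bg``. All cells are drawn
independently, mirroring the conditional-independence premise of the
classifier; a correlated-copy mode duplicates associated domains verbatim to
probe robustness against dependent features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from oxyreq.core_io import BASE_CLASSES, PresenceMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of a synthetic dataset.

    ``class_sizes`` maps class name -> genome count (insertion order is the
    class order). ``facultative_aerobe_overlap``, when set, gives facultative
    genomes the aerobe-associated domains at that intermediate probability
    instead of ``p_out``, mimicking the real aerobe/facultative confusion.
    ``correlated_copies`` appends that many exact duplicates of every
    associated domain.
    """

    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: {c: 30 for c in BASE_CLASSES}
    )
    n_associated: int = 40
    p_in: float = 0.95
    p_out: float = 0.05
    n_background: int = 100
    p_bg: float = 0.5
    seed: int = 0
    facultative_aerobe_overlap: float | None = None
    correlated_copies: int = 0

    def __post_init__(self) -> None:
        for p, name in (
            (self.p_in, "p_in"),
            (self.p_out, "p_out"),
            (self.p_bg, "p_bg"),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.facultative_aerobe_overlap is not None and not (
            0 <= self.facultative_aerobe_overlap <= 1
        ):
            raise ValueError("facultative_aerobe_overlap must be in [0, 1]")
        if self.n_associated < 0 or self.n_background < 0 or self.correlated_copies < 0:
            raise ValueError("counts must be non-negative")
        for cls, n in self.class_sizes.items():
            if n <= 0:
                raise ValueError(f"class {cls!r} must have at least 1 genome")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_sizes)

    def planted_domains(self) -> dict[str, list[str]]:
        """Domain ids of each class's associated block (deterministic layout)."""
        out: dict[str, list[str]] = {}
        j = 0
        for cls in self.classes:
            out[cls] = [f"PFSYN{j + k + 1:05d}" for k in range(self.n_associated)]
            j += self.n_associated
        return out

    def background_domains(self) -> list[str]:
        j = self.n_associated * len(self.classes)
        return [f"PFSYN{j + k + 1:05d}" for k in range(self.n_background)]


def generate(spec: SyntheticSpec) -> tuple[PresenceMatrix, dict[str, str]]:
    """Draw a (PresenceMatrix, label map) pair from the spec; seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    classes = spec.classes
    genome_ids: list[str] = []
    genome_class: list[str] = []
    for cls in classes:
        for _ in range(spec.class_sizes[cls]):
            genome_ids.append(f"g{len(genome_ids) + 1:04d}")
            genome_class.append(cls)
    n_genomes = len(genome_ids)

    planted = spec.planted_domains()
    domain_ids = [d for cls in classes for d in planted[cls]] + spec.background_domains()
    n_domains = len(domain_ids)

    prob = np.full((n_genomes, n_domains), spec.p_out)
    col = 0
    for cls in classes:
        block = slice(col, col + spec.n_associated)
        for i, gcls in enumerate(genome_class):
            if gcls == cls:
                prob[i, block] = spec.p_in
            elif (
                spec.facultative_aerobe_overlap is not None
                and cls == "aerobe"
                and gcls == "facultative"
            ):
                prob[i, block] = spec.facultative_aerobe_overlap
        col += spec.n_associated
    prob[:, col:] = spec.p_bg

    values = (rng.random((n_genomes, n_domains)) < prob).astype(np.uint8)

    if spec.correlated_copies:
        copies = np.tile(values[:, : col], (1, spec.correlated_copies))
        copy_ids = [
            f"{d}C{r + 1}"
            for r in range(spec.correlated_copies)
            for d in domain_ids[:col]
        ]
        values = np.hstack([values, copies])
        domain_ids = domain_ids + copy_ids

    matrix = PresenceMatrix(genome_ids, domain_ids, values)
    labels = dict(zip(genome_ids, genome_class))
    return matrix, labels
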