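"""Dirichlet mock-community generator.

Produces groups of samples with controlled richness and evenness: each
sample's taxon proportions are drawn from a symmetric Dirichlet whose
dimension sets the richness and whose concentration parameter sets the
evenness (high concentration -> near-uniform proportions, NME near 1; low
concentration -> strongly dominated communities, low NME).  This mirrors the
mock-data strategy of working from predetermined abundance structures rather
than from a sequencing error model: there is no sampling noise, no zero
inflation and no taxon correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["GroupSpec", "SyntheticSpec", "simulate"]


@dataclass(frozen=True)
class GroupSpec:
    """One simulated group: label, sample count, richness, Dirichlet concentration."""

    label: str
    n_samples: int
    richness: int
    concentration: float

    def validate(self) -> None:
        if self.n_samples < 1:
            raise InvalidInputError(f"group {self.label!r}: n_samples must be >= 1")
        if self.richness < 2:
            raise InvalidInputError(f"group {self.label!r}: richness must be >= 2")
        if not self.concentration > 0:
            raise InvalidInputError(f"group {self.label!r}: concentration must be > 0")


def _default_groups() -> list[GroupSpec]:
    # Mirrors the bundled ten-biome dataset: one species-richer, uneven group
    # and one species-poorer, even group, five samples each.
    return [
        GroupSpec("Alpha", 5, 5, 0.8),
        GroupSpec("Omega", 5, 3, 15.0),
    ]


@dataclass
class SyntheticSpec:
    """Specification for a synthetic mock data set."""

    groups: list[GroupSpec] = field(default_factory=_default_groups)
    seed: int | None = None

    def validate(self) -> None:
        if not self.groups:
            raise InvalidInputError("spec needs at least one group")
        for g in self.groups:
            g.validate()


def simulate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a mock abundance matrix + metadata from a :class:`SyntheticSpec`.

    Every sample in a group has exactly the group's richness: its proportions
    are a symmetric Dirichlet draw over the first ``richness`` taxon columns,
    with the remaining columns 0.  Reproducible for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_taxa = max(g.richness for g in spec.groups)
    taxa = [f"taxon{i + 1}" for i in range(n_taxa)]
    rows, ids, labels = [], [], []
    for g in spec.groups:
        draws = rng.dirichlet([g.concentration] * g.richness, size=g.n_samples)
        for i in range(g.n_samples):
            row = np.zeros(n_taxa)
            row[: g.richness] = draws[i]
            rows.append(row)
            ids.append(f"{g.label}_{i + 1}")
            labels.append(g.label)
    abundance = pd.DataFrame(rows, index=pd.Index(ids, name="sample"), columns=taxa)
    metadata = pd.DataFrame({"Group": pd.Categorical(labels)}, index=abundance.index)
    return abundance, metadata
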