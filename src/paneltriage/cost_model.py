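"""Reagent-cost comparison: Sanger sequencing vs. a flat-price targeted NGS
panel.

Sanger cost scales linearly with the number of amplicons a phenotype's
candidate genes require (default $10 per amplicon); the NGS panel is a flat
per-sample price (default $580) regardless of how many genes the phenotype
implicates. Labor is excluded by default (it dominates real costs but is not
part of the reagent comparison); a labor multiplier hook exists and defaults
off. Known-family single-amplicon confirmation is modeled as a one-amplicon
panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd


@dataclass(frozen=True)
class CostModel:
    sanger_per_amplicon: float = 10.0
    ngs_per_sample: float = 580.0
    labor_multiplier: Optional[float] = None  # off by default

    def __post_init__(self) -> None:
        if self.sanger_per_amplicon < 0 or self.ngs_per_sample < 0:
            raise ValueError("costs must be >= 0")


@dataclass(frozen=True)
class PhenotypePanel:
    phenotype: str
    genes: tuple[tuple[str, int], ...]  # (gene, amplicon count)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must list at least one gene")
        if any(count < 1 for _, count in self.genes):
            raise ValueError("amplicon counts must be >= 1")


def panel_amplicons(panel: PhenotypePanel) -> int:
    """Total amplicons Sanger sequencing of the whole panel would need."""
    return sum(count for _, count in panel.genes)


@dataclass(frozen=True)
class CostComparison:
    phenotype: str
    total_amplicons: int
    sanger_usd: float
    ngs_usd: float
    cheaper: str  # "sanger", "ngs", or "tie"
    break_even_amplicons: int


def break_even(model: CostModel) -> int:
    """Smallest amplicon count at which NGS becomes strictly cheaper."""
    n = int(model.ngs_per_sample // model.sanger_per_amplicon)
    while n * model.sanger_per_amplicon <= model.ngs_per_sample:
        n += 1
    return n


def compare_costs(panel: PhenotypePanel, model: CostModel = CostModel()) -> CostComparison:
    total = panel_amplicons(panel)
    mult = model.labor_multiplier if model.labor_multiplier is not None else 1.0
    sanger = total * model.sanger_per_amplicon * mult
    ngs = model.ngs_per_sample * mult
    if sanger < ngs:
        cheaper = "sanger"
    elif ngs < sanger:
        cheaper = "ngs"
    else:
        cheaper = "tie"
    return CostComparison(
        phenotype=panel.phenotype,
        total_amplicons=total,
        sanger_usd=sanger,
        ngs_usd=ngs,
        cheaper=cheaper,
        break_even_amplicons=break_even(model),
    )


def load_panels(path: str | Path) -> list[PhenotypePanel]:
    """Load panels from a TSV with columns phenotype, gene, amplicons."""
    df = pd.read_csv(path, sep="\t", comment="#")
    panels = []
    for phenotype, grp in df.groupby("phenotype", sort=False):
        genes = tuple(
            (str(row.gene), int(row.amplicons)) for row in grp.itertuples()
        )
        panels.append(PhenotypePanel(str(phenotype), genes))
    return panels


def builtin_panels() -> list[PhenotypePanel]:
    """The five packaged phenotype panels (immunodeficiency gene panels)."""
    ref = resources.files("paneltriage").joinpath("data/phenotype_panels.tsv")
    with resources.as_file(ref) as path:
        return load_panels(path)
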