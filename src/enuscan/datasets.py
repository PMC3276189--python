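"""Bundled worked-example datasets from the published four-line screen.

Three small tables ship with the package: the per-line, per-class
filtering counts; the mapped-region split of the remaining replacement
variants; and the pedigree genotype counts for the six candidate
mutations. They are inputs (what the screen printed), used to rebuild a
deterministic fixture whose pipeline output must reproduce them.
"""

from __future__ import annotations

from importlib.resources import files
from typing import Dict, Tuple

from .model import FunctionalClass, PedGenotype, PedigreeRecord, Phenotype

Composition = Tuple[int, int, int]  # (total_homozygous, in_dbsnp, in_background)


def _rows(name: str):
    text = files("enuscan.data").joinpath(name).read_text()
    for line in text.splitlines():
        if line and not line.startswith("#"):
            yield line.split("\t")


def load_reported_filter_counts() -> Dict[str, Dict[FunctionalClass, Composition]]:
    """Per-line, per-class (total, in_dbsnp, in_background) compositions."""
    out: Dict[str, Dict[FunctionalClass, Composition]] = {}
    for line_id, fc, total, dbsnp, bg in _rows("enu_lines_filter_counts.tsv"):
        out.setdefault(line_id, {})[FunctionalClass(fc)] = (
            int(total),
            int(dbsnp),
            int(bg),
        )
    return out


def load_reported_region_splits() -> Dict[str, Tuple[int, int]]:
    """Per-line (remaining replacement, of which within mapped region)."""
    return {
        line_id: (int(remaining), int(within))
        for line_id, remaining, within in _rows("enu_lines_mapped_region.tsv")
    }


def load_reported_segregation_counts() -> Dict[Tuple[str, str], Dict[str, int]]:
    """Pedigree genotype counts for the six candidate mutations."""
    out = {}
    for line_id, cand, wt_not, wt_hom, mut_not, mut_hom in _rows(
        "enu_lines_segregation_counts.tsv"
    ):
        out[(line_id, cand)] = {
            "wild_type_not_hom_alt": int(wt_not),
            "wild_type_hom_alt": int(wt_hom),
            "mutant_not_hom_alt": int(mut_not),
            "mutant_hom_alt": int(mut_hom),
        }
    return out


def pedigree_from_counts(
    wild_type_not_hom_alt: int,
    wild_type_hom_alt: int,
    mutant_not_hom_alt: int,
    mutant_hom_alt: int,
    litter_id: str = "L1",
) -> list[PedigreeRecord]:
    """Expand a 2x2 count table into individual pedigree records.

    Non-HOM_ALT embryos are recorded HET; the tests collapse genotypes to
    the HOM_ALT-vs-not dichotomy, so the het/hom-ref split is immaterial.
    """
    records = []
    groups = [
        (Phenotype.WILD_TYPE, PedGenotype.HET, wild_type_not_hom_alt),
        (Phenotype.WILD_TYPE, PedGenotype.HOM_ALT, wild_type_hom_alt),
        (Phenotype.MUTANT, PedGenotype.HET, mutant_not_hom_alt),
        (Phenotype.MUTANT, PedGenotype.HOM_ALT, mutant_hom_alt),
    ]
    n = 0
    for phenotype, genotype, count in groups:
        for _ in range(count):
            n += 1
            records.append(
                PedigreeRecord(f"E{n:04d}", litter_id, phenotype, genotype)
            )
    return records
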