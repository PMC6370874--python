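"""Cohort-level aggregation of per-case driver calls.

Produces the headline numbers for a driver-discovery cohort: per-gene
mutation frequencies (as rounded percentages), VAF summaries over cases
with a measured VAF, and the anatomic-site breakdown.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ameloseq.formats import CohortCase

SITES = ("mandible", "maxilla")
GENOTYPES = ("HRAS", "BRAF", "none")


def round_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer, half away from zero.

    Python's round() rounds half to even; cohort frequency tables
    conventionally round half up (15/24 -> 63, not 62).
    """
    pct = 100.0 * numerator / denominator
    return int(math.floor(pct + 0.5)) if pct >= 0 else -int(math.floor(-pct + 0.5))


@dataclass
class CohortSummary:
    n_cases: int
    n_hras: int
    n_braf: int
    n_wildtype: int
    freq_hras: int  # percent
    freq_braf: int
    freq_mapk: int
    vaf_mean: Optional[float]
    vaf_min: Optional[float]
    vaf_max: Optional[float]
    n_vaf_measured: int
    by_site: dict = field(default_factory=dict)  # (site, genotype) -> count

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_cases",
                "n_hras",
                "n_braf",
                "n_wildtype",
                "freq_hras",
                "freq_braf",
                "freq_mapk",
                "vaf_mean",
                "vaf_min",
                "vaf_max",
                "n_vaf_measured",
            )
        }
        d["by_site"] = {f"{s}:{g}": c for (s, g), c in self.by_site.items()}
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _genotype(case: CohortCase) -> str:
    if case.mutation_call is None:
        return "none"
    gene = case.mutation_call[0].upper()
    return gene if gene in ("HRAS", "BRAF") else "none"


def summarize(cases: Sequence[CohortCase]) -> CohortSummary:
    """Aggregate driver calls into cohort statistics.

    Frequencies are percentages rounded half away from zero. VAF statistics
    cover only cases with a measured VAF: cases confirmed by orthogonal
    assays without exome depth/VAF measurements count toward frequencies
    but not VAF summaries. Permutation-invariant and deterministic.
    """
    if not cases:
        raise ValueError("cannot summarize an empty cohort")
    n = len(cases)
    genos = [_genotype(c) for c in cases]
    n_hras = genos.count("HRAS")
    n_braf = genos.count("BRAF")
    vafs = sorted(c.vaf for c in cases if c.vaf is not None)
    return CohortSummary(
        n_cases=n,
        n_hras=n_hras,
        n_braf=n_braf,
        n_wildtype=n - n_hras - n_braf,
        freq_hras=round_percent(n_hras, n),
        freq_braf=round_percent(n_braf, n),
        freq_mapk=round_percent(n_hras + n_braf, n),
        vaf_mean=(sum(vafs) / len(vafs)) if vafs else None,
        vaf_min=vafs[0] if vafs else None,
        vaf_max=vafs[-1] if vafs else None,
        n_vaf_measured=len(vafs),
        by_site=site_breakdown(cases),
    )


def site_breakdown(cases: Sequence[CohortCase]) -> dict:
    """Counts per anatomic site x genotype; errors on unknown site labels."""
    table = {(s, g): 0 for s in SITES for g in GENOTYPES}
    for c in cases:
        if c.location not in SITES:
            raise ValueError(f"unknown anatomic site {c.location!r} for {c.case_id}")
        table[(c.location, _genotype(c))] += 1
    return table


def write_summary_tsv(summary: CohortSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in summary.to_dict().items():
            if k == "by_site":
                for key, cnt in v.items():
                    fh.write(f"by_site:{key}\t{cnt}\n")
            else:
                fh.write(f"{k}\t{v}\n")
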