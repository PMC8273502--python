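"""Marker-sex concordance: Pearson's chi-squared with Yates' correction.

A sex-linked molecular marker is validated by cross-tabulating its
presence/absence call against phenotypic sex in individuals not used for
discovery. For the resulting 2x2 table the statistic is

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / (R1 * R2 * C1 * C2)

with N the total count, R/C the row/column marginals and N/2 the Yates
continuity correction, clamped at zero so tiny deviations are not inflated.
The p-value is the upper tail of chi-squared with 1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2 as _chi2_dist

__all__ = ["ConcordanceTable", "build_table", "yates_chi2", "association_report"]


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 marker-call x phenotypic-sex counts for one species.

    a: marker-positive females, b: marker-negative females,
    c: marker-positive males,  d: marker-negative males.
    """

    a: int
    b: int
    c: int
    d: int
    species: str = ""

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_table(genotypes: pd.DataFrame, species: str) -> ConcordanceTable:
    """Cross-tabulate marker call by sex for one species.

    ``genotypes`` is a per-individual frame with columns
    (individual, species, sex, marker); sex in {female, male}, marker in
    {positive, negative}. Raises on unknown categories or if the species
    has no individuals.
    """
    from poolsex.io import validate_genotype_table

    sub = validate_genotype_table(genotypes)
    sub = sub[sub["species"] == species]
    if sub.empty:
        raise ValueError(f"no individuals for species {species!r}")
    fem = sub[sub["sex"] == "female"]
    male = sub[sub["sex"] == "male"]
    return ConcordanceTable(
        a=int((fem["marker"] == "positive").sum()),
        b=int((fem["marker"] == "negative").sum()),
        c=int((male["marker"] == "positive").sum()),
        d=int((male["marker"] == "negative").sum()),
        species=species,
    )


def yates_chi2(table: ConcordanceTable) -> tuple[float, float]:
    """Yates-corrected Pearson chi-squared and its two-sided p-value.

    Requires all four marginals (both sexes and both call outcomes
    represented) to be positive; otherwise the statistic is undefined and a
    ``ValueError('degenerate table')`` is raised.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError(
            f"degenerate table ({a},{b},{c},{d}): a zero marginal leaves "
            "the chi-squared statistic undefined"
        )
    dev = max(abs(a * d - b * c) - n / 2, 0.0)
    chi2 = n * dev**2 / (r1 * r2 * c1 * c2)
    p = float(_chi2_dist.sf(chi2, df=1))
    return float(chi2), p


def association_report(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-species concordance table counts, chi2 and p-value.

    Species are reported in order of first appearance; p-values are also
    given formatted to 4 significant digits.
    """
    rows = []
    for species in pd.unique(genotypes["species"]):
        t = build_table(genotypes, species)
        chi2, p = yates_chi2(t)
        rows.append(
            {
                "species": species,
                "positive_females": t.a,
                "negative_females": t.b,
                "positive_males": t.c,
                "negative_males": t.d,
                "chi2": chi2,
                "p_value": p,
                "p_formatted": f"{p:.4g}",
            }
        )
    return pd.DataFrame(rows)
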