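"""Mendelian segregation-ratio tests per cross.

For each mating pair the expected black:yellow class follows from the
parents' carrier genotypes at the causal locus (yellow recessive), and the
observed counts are tested with a 1-df Pearson chi-square goodness-of-fit
(no continuity correction). Crosses with a degenerate expectation
(all-black, all-yellow) are checked for exact concordance instead: a
single off-class individual violates the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import expected_ratio_label

expected_ratio = expected_ratio_label

_EXPECTED_FRACTION_BLACK = {"3:1": 0.75, "1:1": 0.5}


@dataclass(frozen=True)
class SegregationResult:
    cross_label: str
    n_black: int
    n_yellow: int
    observed_ratio: float  # black/yellow; inf encoded for all-black cohorts
    expected_ratio: str  # all-black | 1:1 | 3:1 | all-yellow
    chi2: float
    p: float
    df: int = 1
    concordant: bool | None = None  # degenerate expectations only

    def to_row(self) -> dict:
        return {
            "cross": self.cross_label,
            "n_black": self.n_black,
            "n_yellow": self.n_yellow,
            "observed_ratio": round(self.observed_ratio, 2),
            "expected": self.expected_ratio,
            "chi2": self.chi2,
            "p": self.p,
            "concordant": self.concordant,
        }


def chisq_gof(n_black: int, n_yellow: int, expected: str) -> tuple[float, float]:
    """Pearson chi-square of observed counts against a 3:1 or 1:1 expectation."""
    if n_black < 0 or n_yellow < 0:
        raise ValueError("counts must be non-negative")
    total = n_black + n_yellow
    if total == 0:
        raise ValueError("empty cohort")
    if expected not in _EXPECTED_FRACTION_BLACK:
        raise ValueError(
            f"degenerate expectation {expected!r} has no chi-square test; "
            "use exact concordance"
        )
    fb = _EXPECTED_FRACTION_BLACK[expected]
    exp = np.array([total * fb, total * (1 - fb)])
    obs = np.array([n_black, n_yellow], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def test_cross(
    label: str, n_black: int, n_yellow: int, dam_genotype: str, sire_genotype: str
) -> SegregationResult:
    expected = expected_ratio_label(dam_genotype, sire_genotype)
    total = n_black + n_yellow
    if total == 0:
        raise ValueError(f"empty cohort for cross {label!r}")
    observed = float("inf") if n_yellow == 0 else n_black / n_yellow
    if expected in ("all-black", "all-yellow"):
        ok = n_yellow == 0 if expected == "all-black" else n_black == 0
        return SegregationResult(
            label, n_black, n_yellow, observed, expected, chi2=0.0, p=1.0 if ok else 0.0,
            concordant=ok,
        )
    chi2, p = chisq_gof(n_black, n_yellow, expected)
    return SegregationResult(label, n_black, n_yellow, observed, expected, chi2, p)


test_cross.__test__ = False  # not a pytest item


def segregation_table(
    cohorts: list[tuple[str, list[str]]] | pd.DataFrame,
    plan_genotypes: dict[str, tuple[str, str]],
) -> pd.DataFrame:
    """One SegregationResult row per cross.

    ``cohorts`` is either a list of (label, phenotype list) pairs or a
    frame with columns cross/n_black/n_yellow; ``plan_genotypes`` maps
    each label to the parental causal genotypes.
    """
    rows = []
    if isinstance(cohorts, pd.DataFrame):
        records = [
            (r["cross"], int(r["n_black"]), int(r["n_yellow"])) for _, r in cohorts.iterrows()
        ]
    else:
        records = []
        for label, phenotypes in cohorts:
            phenos = list(phenotypes)
            bad = set(phenos) - {"black", "yellow"}
            if bad:
                raise ValueError(f"unknown phenotypes {bad} in cross {label!r}")
            records.append((label, phenos.count("black"), phenos.count("yellow")))
    for label, nb, ny in records:
        if label not in plan_genotypes:
            raise KeyError(f"cross label {label!r} missing from the mating plan")
        dam_gt, sire_gt = plan_genotypes[label]
        rows.append(test_cross(label, nb, ny, dam_gt, sire_gt).to_row())
    return pd.DataFrame(rows)
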