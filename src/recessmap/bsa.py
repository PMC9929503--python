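"""Three-pool bulk-segregant SNP screening cascade.

The screen works on pooled allele depths from three DNA bulks — the
wild-type line pool (WW), the mutant line pool (YY) and an F1-carrier
pool — and keeps sites where (i) only two alleles are seen, (ii) the WW
pool matches the reference and the YY pool the variant allele while the
F1 pool shows both, and the F1 pool's allele ratio is compatible with
1:1 by a chi-square goodness-of-fit. Survivors are intersected with the
GWAS candidate interval, then with the genome-wide-significant SNP set,
and finally reduced to the perfectly associated SNPs in the F2 panel.
Each stage's in/out counts are recorded in a funnel report.

Because pools are screened on allele-depth fractions rather than called
genotypes, "homozygous" means an off-allele fraction at most ``epsilon``
(default 0.10) at a minimum per-pool depth (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import PeakRegion

POOL_PREFIXES = ("ww", "yy", "het")
REQUIRED_COLUMNS = ["chrom", "pos"] + [
    f"{p}_{k}" for p in POOL_PREFIXES for k in ("ref", "alt")
]


@dataclass
class FunnelReport:
    """Ordered per-stage survivor counts plus the final candidate list."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (name, n_in, n_out)
    candidates: pd.DataFrame | None = None
    status: str = "ok"

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError("funnel stages cannot gain variants")
        self.stages.append((name, int(n_in), int(n_out)))

    @property
    def counts(self) -> list[int]:
        return [n_out for _, _, n_out in self.stages]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "stages": [
                {"stage": s, "n_in": i, "n_out": o} for s, i, o in self.stages
            ],
            "n_final": 0 if self.candidates is None else int(len(self.candidates)),
        }


def _pool_columns(pools: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in pools.columns]
    if missing:
        raise ValueError(f"pool table missing columns: {missing}")


def criterion_biallelic(pools: pd.DataFrame, other_epsilon: float = 0.05) -> pd.Series:
    """Criterion (i): only two allele types across the pools.

    Sites whose third-allele read fraction exceeds ``other_epsilon`` of the
    total depth fail, as do sites with zero depth in every pool.
    """
    _pool_columns(pools)
    depth = sum(pools[f"{p}_{k}"] for p in POOL_PREFIXES for k in ("ref", "alt"))
    other_cols = [f"{p}_other" for p in POOL_PREFIXES if f"{p}_other" in pools.columns]
    other = pools[other_cols].sum(axis=1) if other_cols else pd.Series(0, index=pools.index)
    total = depth + other
    with np.errstate(invalid="ignore"):
        frac_other = np.where(total > 0, other / total, 1.0)
    return pd.Series((total > 0) & (frac_other <= other_epsilon), index=pools.index)


def criterion_opposite_homozygotes(
    pools: pd.DataFrame, epsilon: float = 0.10, min_depth: int = 10
) -> pd.Series:
    """Criterion (ii): WW pool homozygous reference, YY pool homozygous
    variant, F1 pool carrying both alleles; all at adequate depth.

    ``epsilon`` is the off-allele read fraction still called homozygous.
    The 0.10 default tolerates a couple of miscalled reads at ~30x pool
    depth while remaining far below the ~0.5 fraction of a site actually
    segregating within a line.
    """
    _pool_columns(pools)
    ww_d = pools["ww_ref"] + pools["ww_alt"]
    yy_d = pools["yy_ref"] + pools["yy_alt"]
    het_d = pools["het_ref"] + pools["het_alt"]
    deep = (ww_d >= min_depth) & (yy_d >= min_depth) & (het_d >= min_depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        ww_alt_frac = np.where(ww_d > 0, pools["ww_alt"] / ww_d, 1.0)
        yy_ref_frac = np.where(yy_d > 0, pools["yy_ref"] / yy_d, 1.0)
    het_both = (pools["het_ref"] > 0) & (pools["het_alt"] > 0)
    return pd.Series(
        deep & (ww_alt_frac <= epsilon) & (yy_ref_frac <= epsilon) & het_both,
        index=pools.index,
    )


def het_balance_test(
    het_ref: int | np.ndarray, het_alt: int | np.ndarray, alpha: float = 0.001
):
    """Chi-square goodness-of-fit of the F1-pool allele ratio against 1:1.

    chi2 = (ref - alt)^2 / (ref + alt), df = 1; a site *passes* when the
    null of balance is not rejected (p >= alpha). Zero total depth fails.
    Accepts scalars or aligned arrays.

    The default keep rule is deliberately strict (alpha = 0.001): the
    screen's job is to discard grossly imbalanced sites (mismapping,
    duplications), and a looser alpha would discard a fraction alpha of
    genuinely balanced sites — including the causal one — for no gain in
    specificity, since within-line segregating sites are already caught
    by the opposite-homozygote criterion.
    """
    ref = np.asarray(het_ref, dtype=float)
    alt = np.asarray(het_alt, dtype=float)
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(total > 0, (ref - alt) ** 2 / np.where(total > 0, total, 1), np.inf)
    p = stats.chi2.sf(chi2, df=1)
    ok = (total > 0) & (p >= alpha)
    if np.isscalar(het_ref) and np.isscalar(het_alt):
        return float(chi2), float(p), bool(ok)
    return chi2, p, ok


def perfect_association(genotypes: np.ndarray, phenotypes: np.ndarray) -> np.ndarray:
    """Per-variant flag: every non-missing affected individual is hom-alt
    and every non-missing unaffected one carries at least one ref allele.

    ``genotypes`` is (n_variants, n_samples) dosage with -1 missing;
    ``phenotypes`` is an array of 'black'/'yellow' labels (or 0/1 with
    1 = yellow).
    """
    G = np.asarray(genotypes)
    ph = np.asarray(phenotypes)
    if ph.dtype.kind in "UO":
        bad = set(ph) - {"black", "yellow"}
        if bad:
            raise ValueError(f"unknown phenotype labels: {bad}")
        case = ph == "yellow"
    else:
        case = ph.astype(int) == 1
    Gy = G[:, case]
    Gb = G[:, ~case]
    yellow_ok = ((Gy == 2) | (Gy < 0)).all(axis=1)
    black_ok = ((Gb == 0) | (Gb == 1) | (Gb < 0)).all(axis=1)
    informative = (G >= 0).any(axis=1)
    return yellow_ok & black_ok & informative


def apply_cascade(
    variants: pd.DataFrame,
    pools: pd.DataFrame,
    region: PeakRegion | None,
    gwas_significant: set[tuple[str, int]],
    genotypes: np.ndarray | None,
    phenotypes: np.ndarray | None,
    epsilon: float = 0.10,
    min_depth: int = 10,
    alpha_balance: float = 0.001,
    other_epsilon: float = 0.05,
) -> FunnelReport:
    """Run the full screening cascade and record the funnel.

    Stage order, as the screen defines it: allele criteria (i) + (ii) +
    F1 balance test, then candidate-interval intersection, then overlap
    with the genome-wide-significant set, then perfect association in the
    F2 panel (requires ``genotypes``/``phenotypes`` aligned to ``variants``).
    """
    if len(variants) != len(pools):
        raise ValueError("variants and pool counts must align row-for-row")
    report = FunnelReport()
    n0 = len(variants)

    c1 = criterion_biallelic(pools, other_epsilon)
    c2 = criterion_opposite_homozygotes(pools, epsilon, min_depth)
    _, _, balanced = het_balance_test(
        pools["het_ref"].to_numpy(), pools["het_alt"].to_numpy(), alpha_balance
    )
    stage1 = (c1 & c2 & pd.Series(balanced, index=pools.index)).to_numpy()
    report.add("allele criteria + 1:1 balance", n0, stage1.sum())

    if region is None:
        report.status = "no-candidate-region"
        report.candidates = variants.iloc[0:0].copy()
        return report

    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    in_region = stage1 & (chroms == region.chrom) & (pos >= region.start) & (pos <= region.end)
    report.add("within candidate interval", stage1.sum(), in_region.sum())

    keys = list(zip(chroms, pos))
    overlap = in_region & np.array([k in gwas_significant for k in keys], dtype=bool)
    report.add("overlap GWAS-significant", in_region.sum(), overlap.sum())

    if genotypes is None or phenotypes is None:
        raise ValueError("panel genotypes and phenotypes are required for the final stage")
    perfect = overlap & perfect_association(np.asarray(genotypes), phenotypes)
    report.add("perfect association", overlap.sum(), perfect.sum())

    report.candidates = variants.loc[perfect].reset_index(drop=True)
    return report
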