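"""Per-SNP case-control association over the F2 panel.

Each site is tested with a logistic regression of phenotype on additive
alt-allele dosage (intercept + dosage, Newton-Raphson / IRLS, Wald p on
the dosage coefficient). Perfectly or quasi-perfectly associated sites
cannot yield finite logistic estimates, so on non-convergence or an
exploding coefficient the test falls back to a two-sided Fisher's exact
test on the 2x2 allelic table; the ``method`` column records which route
produced each p-value. Genome-wide significance uses the Bonferroni rule
-log10(alpha / n_snps) with alpha = 0.01.

The Newton solver is vectorised across sites so that whole-scan and
calibration simulations stay cheap; the fit is cross-checked against
generic maximum-likelihood optimisers in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: coefficient magnitude beyond which a fit is treated as separated
SEPARATION_BETA = 15.0
_MAX_ITER = 40
_TOL = 1e-10


@dataclass(frozen=True)
class SiteQC:
    mean_depth: float
    call_rate: float
    n_alleles: int = 2


@dataclass(frozen=True)
class PeakRegion:
    chrom: str
    start: int
    end: int
    n_significant: int

    @property
    def span_bp(self) -> int:
        # end - start reproduces the printed Mb span convention
        return self.end - self.start

    @property
    def span_mb(self) -> float:
        return round(self.span_bp / 1e6, 2)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def site_filter(
    genotypes: np.ndarray,
    depths: np.ndarray,
    min_mean_dp: float = 5.0,
    max_mean_dp: float = 250.0,
    min_call_rate: float = 0.95,
    biallelic: bool = True,
) -> tuple[bool, SiteQC]:
    """Depth/missingness site QC (thresholds inclusive)."""
    genotypes = np.asarray(genotypes)
    depths = np.asarray(depths, dtype=float)
    if genotypes.size == 0:
        raise ValueError("site has no samples")
    call_rate = float((genotypes >= 0).mean())
    mean_depth = float(depths.mean()) if depths.size else 0.0
    qc = SiteQC(mean_depth=mean_depth, call_rate=call_rate, n_alleles=2 if biallelic else 3)
    ok = (
        biallelic
        and min_mean_dp <= mean_depth <= max_mean_dp
        and call_rate >= min_call_rate
    )
    return ok, qc


def bonferroni_threshold(n_snps: int, alpha: float = 0.01) -> float:
    """Genome-wide -log10(p) significance cutoff, -log10(alpha / n_snps)."""
    if n_snps < 1:
        raise ValueError("need at least one SNP to set a threshold")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_snps))


def _logistic_newton_batch(
    dosage: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton/IRLS fit of y ~ 1 + dosage, one model per row of ``dosage``.

    Returns (beta, se, converged) for the dosage coefficient. Rows where
    the Hessian degenerates or the solver fails to converge are flagged.
    """
    D = np.atleast_2d(np.asarray(dosage, dtype=float))
    y = np.asarray(y, dtype=float)
    m = D.shape[0]
    b0 = np.zeros(m)
    b1 = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    active = np.ones(m, dtype=bool)
    for _ in range(_MAX_ITER):
        eta = np.clip(b0[:, None] + b1[:, None] * D, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        r = y[None, :] - mu
        g0 = r.sum(axis=1)
        g1 = (r * D).sum(axis=1)
        a = w.sum(axis=1)
        b = (w * D).sum(axis=1)
        c = (w * D * D).sum(axis=1)
        det = a * c - b * b
        ok = det > 1e-12
        step0 = np.where(ok, (c * g0 - b * g1) / np.where(ok, det, 1.0), 0.0)
        step1 = np.where(ok, (a * g1 - b * g0) / np.where(ok, det, 1.0), 0.0)
        # stabilise early iterations against overshoot on near-separated data
        norm = np.maximum(1.0, np.maximum(np.abs(step0), np.abs(step1)) / 10.0)
        step0, step1 = step0 / norm, step1 / norm
        upd = active & ok
        b0 = np.where(upd, b0 + step0, b0)
        b1 = np.where(upd, b1 + step1, b1)
        done = (np.abs(step0) < _TOL) & (np.abs(step1) < _TOL) & ok
        converged |= active & done
        active &= ~done & ok
        if not active.any():
            break
    eta = np.clip(b0[:, None] + b1[:, None] * D, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    a = w.sum(axis=1)
    b = (w * D).sum(axis=1)
    c = (w * D * D).sum(axis=1)
    det = a * c - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 1e-12, a / det, np.inf))
    return b1, se, converged


def _allelic_table(dosage: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2x2 allele-count table [[case_alt, case_ref], [control_alt, control_ref]]."""
    case = y == 1
    case_alt = int(dosage[case].sum())
    case_ref = int(2 * case.sum() - case_alt)
    ctrl_alt = int(dosage[~case].sum())
    ctrl_ref = int(2 * (~case).sum() - ctrl_alt)
    return np.array([[case_alt, case_ref], [ctrl_alt, ctrl_ref]])


def logistic_assoc(dosage: np.ndarray, phenotype: np.ndarray) -> dict:
    """Association test at one site; see module docstring for the fallback rule."""
    dosage = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("phenotype must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes must be present")
    if np.ptp(dosage) == 0:
        return {"beta": None, "p": 1.0, "method": "fisher_allelic", "degenerate": True}
    beta, se, converged = _logistic_newton_batch(dosage[None, :], y)
    beta, se, conv = float(beta[0]), float(se[0]), bool(converged[0])
    if conv and abs(beta) <= SEPARATION_BETA and np.isfinite(se):
        z = beta / se
        p = float(2 * stats.norm.sf(abs(z)))
        return {"beta": beta, "p": p, "method": "logistic", "degenerate": False}
    table = _allelic_table(dosage, y)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {"beta": None, "p": p, "method": "fisher_allelic", "degenerate": False}


def genome_scan(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Association scan over pre-filtered sites.

    ``genotypes`` is (n_sites, n_samples) dosage with -1 missing;
    ``phenotypes`` is 0/1 per sample (1 = affected/yellow). Returns the
    per-site result table (Manhattan-ready) and the Bonferroni threshold
    computed from the number of scanned sites.
    """
    G = np.asarray(genotypes)
    y = np.asarray(phenotypes, dtype=int)
    m = len(variants)
    if m == 0:
        raise ValueError("no sites to scan")
    if G.shape != (m, len(y)):
        raise ValueError("genotype matrix does not match variants x samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both phenotype classes must be present")

    threshold = bonferroni_threshold(m, alpha)

    # batch fit on mean-imputed copies; sites with missing calls, separation
    # or degenerate dosage are re-done exactly, one by one
    any_missing = (G < 0).any(axis=1)
    Df = G.astype(float)
    Df[Df < 0] = np.nan
    col_ok = ~np.isnan(Df)
    betas = np.full(m, np.nan)
    ps = np.full(m, np.nan)
    methods = np.full(m, "logistic", dtype=object)

    clean = ~any_missing & (np.ptp(G, axis=1) > 0)
    if clean.any():
        b, se, conv = _logistic_newton_batch(Df[clean], y)
        z = np.where(se > 0, b / se, 0.0)
        p = 2 * stats.norm.sf(np.abs(z))
        good = conv & (np.abs(b) <= SEPARATION_BETA) & np.isfinite(se)
        idx = np.flatnonzero(clean)
        betas[idx[good]] = b[good]
        ps[idx[good]] = p[good]
        for i in idx[~good]:
            res = logistic_assoc(G[i], y)
            betas[i] = np.nan if res["beta"] is None else res["beta"]
            ps[i] = res["p"]
            methods[i] = res["method"]
    for i in np.flatnonzero(~clean):
        keep = col_ok[i]
        if keep.sum() == 0 or len(np.unique(y[keep])) < 2:
            ps[i], methods[i] = 1.0, "fisher_allelic"
            continue
        res = logistic_assoc(G[i][keep], y[keep])
        betas[i] = np.nan if res["beta"] is None else res["beta"]
        ps[i] = res["p"]
        methods[i] = res["method"]

    ps = np.clip(ps, np.nextafter(0, 1), 1.0)
    neglog = -np.log10(ps)
    out = variants.reset_index(drop=True).copy()
    out["beta"] = betas
    out["p"] = ps
    out["neglog10p"] = neglog
    out["method"] = methods
    out["significant"] = neglog >= threshold
    return out, threshold


def peak_region(results: pd.DataFrame) -> PeakRegion | None:
    """Candidate interval: min..max position of significant SNPs on the
    chromosome carrying the smallest p (ties broken lexicographically).
    Returns None when nothing is significant."""
    sig = results[results["significant"]]
    if len(sig) == 0:
        return None
    best_p = sig["p"].min()
    chrom = sorted(sig.loc[sig["p"] == best_p, "chrom"].unique())[0]
    on = sig[sig["chrom"] == chrom]
    return PeakRegion(
        chrom=chrom,
        start=int(on["pos"].min()),
        end=int(on["pos"].max()),
        n_significant=int(len(on)),
    )
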