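"""Single-annotation-class gene-based tests.

Each annotation class gets its own gene-level test, following the default
forms: coding and UTR variants are aggregated with Q-type tests per subclass
(missense/nonsense/synonymous; 3'/5' UTR) and combined across subclasses
with ACAT (or HMP); distance-to-TSS weighting uses ACAT/HMP over
single-variant p-values with exponential proximity weights across an alpha
grid; enhancer variants are aggregated with a confidence-weighted Q-type
statistic; eQTL predictive weights give per-tissue TWAS z-scores combined
across tissues (CT-TWAS: CT-Q, CT-M, CT-A, CT-H).

A class test that has no variants for a gene returns ``None`` (absent-result
sentinel), never an error; the omnibus layer skips absent classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core_tests import (
    TestOutcome,
    acat_combine,
    hmp_combine,
    mixture_chisq_sf,
    mvn_rectangle_prob,
    qtype_test,
)
from .io_ld import GeneModel, LDProvider, SummaryStatTable, TissueWeightMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_DTSS_WINDOW",
    "TissueTWASResult",
    "coding_test",
    "utr_test",
    "dtss_test",
    "dtss_weights",
    "enhancer_test",
    "twas_single_tissue",
    "cross_tissue_correlation",
    "ct_twas",
    "socs_test",
    "gene_class_tests",
]

#: exponential decay rates (1/bp) for distance-to-TSS weights
DEFAULT_ALPHA_GRID = (1e-4, 5e-5, 1e-5, 5e-6)

#: variants farther than this from the TSS are excluded from dTSS tests (bp)
DEFAULT_DTSS_WINDOW = 500_000

_COMBINERS = {"acat": acat_combine, "hmp": hmp_combine}


def _combine(pvals, combiner: str, weights=None) -> float:
    try:
        fn = _COMBINERS[combiner]
    except KeyError:
        raise ValueError(f"unknown combiner {combiner!r}") from None
    return fn(pvals, weights)


def _subclass_stratified_test(
    gene: str,
    cls: str,
    stats: SummaryStatTable,
    annotations,
    ld: LDProvider,
    combiner: str,
) -> TestOutcome | None:
    """Q-type per subclass, then equal-weight ACAT/HMP across subclasses."""
    rows = annotations.for_gene(gene, cls)
    if rows.empty:
        logger.debug("no %s variants for gene %s", cls, gene)
        return None
    keys_all = annotations.variant_keys(rows)
    present = [k in stats for k in keys_all]
    if not any(present):
        return None
    sub_results: dict[str, TestOutcome] = {}
    for subclass, grp in rows[present].groupby("subclass", sort=True):
        keys = annotations.variant_keys(grp)
        keys = [k for k in keys if k in stats]
        if not keys:
            continue
        Z = stats.z_for(keys)
        R = ld.ld(keys)
        sub_results[str(subclass)] = qtype_test(Z, np.ones(len(keys)), R)
    if not sub_results:
        return None
    labels = sorted(sub_results)
    pvals = [sub_results[s].p for s in labels]
    p = _combine(pvals, combiner)
    stat = float(sum(sub_results[s].stat for s in labels))
    m = int(sum(sub_results[s].m for s in labels))
    return TestOutcome(stat, p, f"{cls}:{combiner}", m,
                       {"subclasses": {s: sub_results[s].p for s in labels}})


def coding_test(gene, stats, annotations, ld, combiner: str = "acat"):
    """Coding-class gene test: Q-type within each coding consequence
    subclass, combined across subclasses. Returns None when the gene has no
    coding variants in the harmonized statistics."""
    return _subclass_stratified_test(gene, "coding", stats, annotations, ld, combiner)


def utr_test(gene, stats, annotations, ld, combiner: str = "acat"):
    """UTR-class gene test over the 3' and 5' UTR subclasses."""
    return _subclass_stratified_test(gene, "utr", stats, annotations, ld, combiner)


def dtss_weights(distances, alpha: float, window: int = DEFAULT_DTSS_WINDOW) -> np.ndarray:
    """Exponential proximity weights w(alpha) = exp(-alpha * |d|); positions
    beyond the window get weight 0 (caller excludes them)."""
    d = np.abs(np.asarray(distances, dtype=float))
    w = np.exp(-alpha * d)
    w[d > window] = 0.0
    return w


def dtss_test(
    gene_model: GeneModel,
    stats: SummaryStatTable,
    alpha_grid=DEFAULT_ALPHA_GRID,
    window: int = DEFAULT_DTSS_WINDOW,
    combiner: str = "acat",
) -> TestOutcome | None:
    """Distance-to-TSS weighted test.

    For each decay rate alpha the single-variant p-values are combined with
    ACAT/HMP using weights exp(-alpha*dTSS); the per-alpha p-values are then
    combined across the grid with equal weights. O(m) per alpha; no LD
    required.
    """
    df = stats.df
    on_chrom = df["chrom"] == gene_model.chrom
    d = np.abs(df["pos"].to_numpy() - gene_model.tss)
    keep = on_chrom.to_numpy() & (d <= window)
    if not keep.any():
        return None
    pvals = df["p"].to_numpy()[keep]
    dist = d[keep]
    per_alpha = []
    for alpha in alpha_grid:
        w = np.exp(-alpha * dist)
        per_alpha.append(_combine(pvals, combiner, w))
    p = _combine(per_alpha, combiner)
    return TestOutcome(float(-np.log10(max(p, 1e-300))), p, f"dtss:{combiner}",
                       int(keep.sum()), {"per_alpha": dict(zip(alpha_grid, per_alpha))})


def enhancer_test(
    gene: str,
    stats: SummaryStatTable,
    annotations,
    ld: LDProvider,
    form: str = "qtype",
) -> TestOutcome | None:
    """Enhancer-weighted gene test.

    ``qtype``: T = sum_i sum_j w_ik Z_ij^2 over enhancers i with confidence
    weight w_ik and member variants j; a variant in several enhancers of the
    gene contributes once per enhancer, i.e. its effective weight is the sum
    of the relevant w_ik. Null: mixture chi-squared. ``acat``/``hmp``:
    confidence-weighted combination of single-variant p-values.
    """
    rows = annotations.for_gene(gene, "enhancer")
    if rows.empty:
        return None
    keys_all = annotations.variant_keys(rows)
    present = np.array([k in stats for k in keys_all])
    rows = rows[present]
    if rows.empty:
        return None
    # per-variant effective weight: sum of confidence weights over enhancers
    weight_by_key: dict = {}
    for key, w in zip(annotations.variant_keys(rows), rows["weight"]):
        weight_by_key[key] = weight_by_key.get(key, 0.0) + float(w)
    keys = sorted(weight_by_key, key=lambda k: (k.chrom, k.pos, k.ref, k.alt))
    w = np.array([weight_by_key[k] for k in keys])
    if not np.any(w > 0):
        raise ValueError(f"all enhancer weights are zero for gene {gene}")
    if form == "qtype":
        Z = stats.z_for(keys)
        R = ld.ld(keys)
        out = qtype_test(Z, w, R)
        out.method = "enhancer:qtype"
        return out
    if form in _COMBINERS:
        pvals = stats.p_for(keys)
        p = _combine(pvals, form, w)
        return TestOutcome(float(-np.log10(max(p, 1e-300))), p, f"enhancer:{form}", len(keys))
    raise ValueError(f"unknown enhancer test form {form!r}")


@dataclass
class TissueTWASResult:
    """Per-tissue TWAS z-score S = b'Z / sqrt(b'Rb) and its two-sided p."""

    gene: str
    tissue: str
    S: float
    p: float
    m_variants: int
    n_missing: int = 0


def twas_single_tissue(
    gene: str,
    tissue: str,
    stats: SummaryStatTable,
    weights: TissueWeightMatrix,
    ld: LDProvider,
    max_missing_fraction: float = 0.5,
) -> TissueTWASResult | None:
    """Summary-statistic TWAS for one gene/tissue.

    Weight variants missing from the GWAS are dropped without rescaling the
    remaining weights (the missing fraction is recorded); if more than
    ``max_missing_fraction`` of the absolute weight mass is missing, or the
    denominator b'Rb is degenerate, an absent-result sentinel is returned.
    """
    variants, b = weights.get(gene, tissue)
    present = np.array([v in stats for v in variants])
    if not present.any():
        return None
    mass = np.abs(b)
    missing_mass = float(mass[~present].sum()) / float(mass.sum())
    if missing_mass > max_missing_fraction:
        logger.info("twas %s/%s: %.0f%% of weight mass missing; skipping",
                    gene, tissue, 100 * missing_mass)
        return None
    keys = [v for v, keep in zip(variants, present) if keep]
    bb = b[present]
    R = ld.ld(keys)
    denom = float(bb @ R.R @ bb)
    if denom <= 1e-10:
        logger.info("twas %s/%s: degenerate denominator", gene, tissue)
        return None
    S = float(bb @ stats.z_for(keys)) / math.sqrt(denom)
    p = 2.0 * float(norm.sf(abs(S)))
    return TissueTWASResult(gene, tissue, S, p, len(keys), int((~present).sum()))


def cross_tissue_correlation(
    gene: str,
    tissues,
    stats: SummaryStatTable,
    weights: TissueWeightMatrix,
    ld: LDProvider,
) -> np.ndarray:
    """Correlation matrix of per-tissue TWAS z-scores:
    [R_S]_tt' = b_t'R b_t' / sqrt((b_t'R b_t)(b_t''R b_t''))."""
    # union of weight variants present in the stats, one joint LD computation
    union: list = []
    seen = set()
    per_tissue: list[tuple[np.ndarray, np.ndarray]] = []
    for t in tissues:
        variants, b = weights.get(gene, t)
        keep = [i for i, v in enumerate(variants) if v in stats]
        kv = [variants[i] for i in keep]
        per_tissue.append((kv, b[keep]))
        for v in kv:
            if v not in seen:
                seen.add(v)
                union.append(v)
    R = ld.ld(union).R
    pos = {v: i for i, v in enumerate(union)}
    B = np.zeros((len(tissues), len(union)))
    for row, (kv, bb) in enumerate(per_tissue):
        for v, w in zip(kv, bb):
            B[row, pos[v]] += w
    G = B @ R @ B.T
    d = np.sqrt(np.diag(G))
    if np.any(d <= 1e-10):
        raise ValueError(f"degenerate tissue weight vector for gene {gene}")
    RS = G / np.outer(d, d)
    np.fill_diagonal(RS, 1.0)
    return np.clip(RS, -1.0, 1.0)


def ct_twas(
    gene: str,
    stats: SummaryStatTable,
    weights: TissueWeightMatrix,
    ld: LDProvider,
    method: str = "ct-a",
    eps: float = 1e-3,
    seed: int = 0,
) -> TestOutcome | None:
    """Cross-tissue TWAS aggregation over the gene's tissues.

    ct-q: sum of squared tissue z-scores, mixture chi-squared null with the
    eigenvalues of the cross-tissue correlation matrix R_S;
    ct-m: max |S_t| with an MVN rectangle p-value over tissues;
    ct-a / ct-h: ACAT / HMP over per-tissue two-sided p-values (the default
    is ct-a). Tissue-level results are kept in diagnostics.
    """
    tissues = weights.tissues_for(gene)
    if not tissues:
        return None
    results = []
    for t in tissues:
        r = twas_single_tissue(gene, t, stats, weights, ld)
        if r is not None:
            results.append(r)
    if not results:
        return None
    S = np.array([r.S for r in results])
    pvals = np.array([r.p for r in results])
    diag = {"tissues": {r.tissue: (r.S, r.p) for r in results}}
    if len(results) == 1:
        return TestOutcome(float(S[0]), float(pvals[0]), f"cttwas:{method}", 1, diag)
    if method in ("ct-a", "ct-h"):
        p = _combine(pvals, "acat" if method == "ct-a" else "hmp")
        return TestOutcome(float(np.sum(S**2)), p, f"cttwas:{method}", len(results), diag)
    RS = cross_tissue_correlation(gene, [r.tissue for r in results], stats, weights, ld)
    RS = (1.0 - eps) * RS + eps * np.eye(len(results))  # ridge for eigen/rectangle
    if method == "ct-q":
        stat = float(np.sum(S**2))
        lam = np.clip(np.linalg.eigvalsh(RS), 0.0, None)
        p, info = mixture_chisq_sf(stat, lam, return_info=True)
        diag.update(info)
        return TestOutcome(stat, p, "cttwas:ct-q", len(results), diag)
    if method == "ct-m":
        t_abs = float(np.max(np.abs(S)))
        rect, err = mvn_rectangle_prob(
            np.full(len(results), -t_abs), np.full(len(results), t_abs), RS, seed=seed
        )
        p = max(1.0 - rect, float(pvals.min()))
        diag["rect_error"] = err
        return TestOutcome(t_abs**2, p, "cttwas:ct-m", len(results), diag)
    raise ValueError(f"unknown CT-TWAS method {method!r}")


def socs_test(
    gene_model: GeneModel,
    stats: SummaryStatTable,
    ld: LDProvider,
    window: int = 500_000,
) -> TestOutcome | None:
    """Annotation-agnostic sum-of-chi-squares baseline: equal-weight Q-type
    over all variants within ``window`` bp of the gene body."""
    df = stats.df
    keep = (df["chrom"] == gene_model.chrom).to_numpy()
    dist = np.array([gene_model.body_distance(int(p)) for p in df["pos"]])
    keep &= dist <= window
    if not keep.any():
        return None
    keys = [k for k, kk in zip(stats.keys(), keep) if kk]
    Z = stats.z_for(keys)
    R = ld.ld(keys)
    out = qtype_test(Z, np.ones(len(keys)), R)
    out.method = "socs"
    return out


def gene_class_tests(
    gene_model: GeneModel,
    stats: SummaryStatTable,
    annotations,
    weights: TissueWeightMatrix | None,
    ld: LDProvider,
    combiner: str = "acat",
    ct_method: str = "ct-a",
    alpha_grid=DEFAULT_ALPHA_GRID,
    dtss_window: int = DEFAULT_DTSS_WINDOW,
) -> dict[str, TestOutcome]:
    """All available single-annotation class tests for one gene; absent
    classes are simply missing from the returned dict."""
    gene = gene_model.gene
    out: dict[str, TestOutcome] = {}
    res = coding_test(gene, stats, annotations, ld, combiner)
    if res is not None:
        out["coding"] = res
    res = utr_test(gene, stats, annotations, ld, combiner)
    if res is not None:
        out["utr"] = res
    res = dtss_test(gene_model, stats, alpha_grid, dtss_window, combiner)
    if res is not None:
        out["dtss"] = res
    res = enhancer_test(gene, stats, annotations, ld)
    if res is not None:
        out["enhancer"] = res
    if weights is not None:
        res = ct_twas(gene, stats, weights, ld, ct_method)
        if res is not None:
            out["cttwas"] = res
    return out
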