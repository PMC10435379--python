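"""Population structure: LD pruning, PCA with projection, BIC-based
informative-PC selection, the iterative HMM long-range-LD (LRLD) detector,
regional ancestry outliers, local PCA, and pairwise Weir-Cockerham Fst.

Long-range LD regions (inversions, HLA and friends) inflate the loadings of
particular genomic intervals and distort leading principal components.  The
detector treats presence in such a region as the hidden state of a two-state
HMM along each chromosome: transition probabilities follow genetic distance
(recombination), and the per-variant evidence is the posterior that its
squared loading Z-score comes from the inflated component of a two-component
scaled-chi-square mixture.  Variants with posterior > 0.5 form regions;
nearby regions are merged; detected regions are removed and the PCA
repeated until no further regions appear on any informative PC (nor the
next, non-informative one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from sklearn.linear_model import LogisticRegression

from .data import MISSING, GeneticMap, GenotypeDataset

# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    calls: np.ndarray,
    positions: np.ndarray | None = None,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Sliding-window greedy LD pruning; returns kept variant indices.

    Within each window, while any kept pair has r-squared above the
    threshold, the member with the lower MAF is removed (ties remove the
    later position).  Caller applies MAF/call-rate/HWE pre-filters.
    """
    g = np.where(calls == MISSING, np.nan, calls).astype(float)
    m = g.shape[1]
    mean = np.nanmean(g, axis=0)
    maf = np.minimum(mean / 2.0, 1 - mean / 2.0)
    keep = np.ones(m, dtype=bool)
    for start in range(0, max(m - 1, 1), step_snps):
        idx = np.flatnonzero(keep[start:start + window_snps]) + start
        if idx.size < 2:
            continue
        sub = g[:, idx]
        col = sub - np.nanmean(sub, axis=0)
        col = np.where(np.isnan(col), 0.0, col)
        denom = np.sqrt((col**2).sum(axis=0))
        denom[denom == 0] = np.inf
        corr = (col.T @ col) / np.outer(denom, denom)
        r2 = corr**2
        np.fill_diagonal(r2, 0.0)
        active = np.ones(idx.size, dtype=bool)
        while True:
            r2a = np.where(np.outer(active, active), r2, 0.0)
            i, j = np.unravel_index(np.argmax(r2a), r2a.shape)
            if r2a[i, j] <= r2_threshold:
                break
            vi, vj = idx[i], idx[j]
            if maf[vi] < maf[vj]:
                drop = i
            elif maf[vj] < maf[vi]:
                drop = j
            else:
                drop = i if vi > vj else j  # tie: drop the later position
            active[drop] = False
        keep[idx[~active]] = False
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Truncated PCA of standardised genotypes.

    scores: (n_samples, k); loadings: (n_variants, k) — right singular
    vectors, so that standardised genotypes @ loadings reproduces scores;
    eigenvalues: variance explained per PC; mean/scale: per-variant
    standardisation parameters; variant_idx: columns used.
    """

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    variant_idx: np.ndarray


def _standardise(calls: np.ndarray, mean=None, scale=None):
    g = np.where(calls == MISSING, np.nan, calls).astype(float)
    if mean is None:
        mean = np.nanmean(g, axis=0)
        p_hat = mean / 2.0
        scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    x = (g - mean) / np.where(scale == 0, np.inf, scale)
    return np.where(np.isnan(x), 0.0, x), mean, scale


def run_pca(
    calls: np.ndarray,
    variant_idx: np.ndarray | None = None,
    n_pcs: int = 10,
) -> PCAResult:
    """PCA of per-variant standardised genotypes (missing set to the mean).

    Genotypes are centred at 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat));
    monomorphic variants are dropped with a warning.
    """
    if variant_idx is None:
        variant_idx = np.arange(calls.shape[1])
    variant_idx = np.asarray(variant_idx)
    sub = calls[:, variant_idx]
    x, mean, scale = _standardise(sub)
    poly = scale > 0
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic variants from PCA")
        variant_idx = variant_idx[poly]
        x, mean, scale = x[:, poly], mean[poly], scale[poly]
    n = x.shape[0]
    k = min(n_pcs, min(x.shape) - 1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # sign convention: largest-magnitude loading positive
    signs = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    vt = vt * signs[:, None]
    u = u * signs[None, :]
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        eigenvalues=s**2 / max(n - 1, 1),
        mean=mean,
        scale=scale,
        variant_idx=variant_idx,
    )


def project_samples(pca: PCAResult, calls: np.ndarray,
                    max_missing: float = 0.2) -> np.ndarray:
    """Project new samples onto existing PCs via the variant loadings."""
    sub = calls[:, pca.variant_idx]
    miss = (sub == MISSING).mean(axis=1)
    if (miss > max_missing).any():
        warnings.warn(
            f"{int((miss > max_missing).sum())} samples exceed "
            f"{max_missing:.0%} missingness on the projection variant set")
    if (miss >= 1.0).any():
        raise ValueError("sample with no genotypes on the projection variant set")
    x, _, _ = _standardise(sub, pca.mean, pca.scale)
    return x @ pca.loadings


# ---------------------------------------------------------------------------
# informative-PC selection


def select_informative_pcs(
    scores: np.ndarray,
    labels,
    model: str = "multinomial",
    max_pcs: int | None = None,
) -> dict:
    """Number of leading PCs that keep reducing BIC when added to a model
    predicting ``labels``.

    model='multinomial': categorical labels (recruitment region);
    'linear_2d': two-column continuous response (latitude, longitude);
    'binary': 0/1 labels.  Returns {'k', 'bics'} where k is the largest
    prefix length such that every added PC reduced BIC.
    """
    s = np.asarray(scores, dtype=float)
    n = s.shape[0]
    max_pcs = min(max_pcs or s.shape[1], s.shape[1])
    bics = [_bic_for(model, s[:, :0], labels, n)]
    k = 0
    for j in range(1, max_pcs + 1):
        bic = _bic_for(model, s[:, :j], labels, n)
        bics.append(bic)
        if bic < bics[k]:
            k = j
        else:
            break
    return {"k": k, "bics": bics}


def _bic_for(model: str, x: np.ndarray, labels, n: int) -> float:
    if model == "multinomial":
        y = pd.Categorical(pd.Series(labels).astype(str))
        r = len(y.categories)
        if r < 2:
            return 0.0
        codes = np.asarray(y.codes)
        if x.shape[1] == 0:
            counts = np.bincount(codes, minlength=r)
            probs = counts / n
            ll = float(np.sum(counts * np.log(np.where(probs > 0, probs, 1))))
            n_par = r - 1
        else:
            clf = LogisticRegression(C=np.inf, max_iter=2000)
            clf.fit(x, codes)
            prob = clf.predict_proba(x)
            ll = float(np.sum(np.log(prob[np.arange(n), codes] + 1e-300)))
            n_par = (x.shape[1] + 1) * (r - 1)
        return -2 * ll + n_par * np.log(n)
    if model == "linear_2d":
        ymat = np.asarray(labels, dtype=float)
        if ymat.ndim == 1:
            ymat = ymat[:, None]
        design = np.column_stack([np.ones(n), x]) if x.shape[1] else np.ones((n, 1))
        ll = 0.0
        n_par = 0
        for c in range(ymat.shape[1]):
            beta, *_ = np.linalg.lstsq(design, ymat[:, c], rcond=None)
            resid = ymat[:, c] - design @ beta
            sigma2 = max(float(np.mean(resid**2)), 1e-12)
            ll += -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
            n_par += design.shape[1] + 1
        return -2 * ll + n_par * np.log(n)
    if model == "binary":
        y = np.asarray(pd.Series(labels).astype(int))
        if len(np.unique(y)) < 2:
            return 0.0
        design = np.column_stack([np.ones(n), x])
        from ._logistic import fit_null
        _, ll = fit_null(y.astype(float), design)
        return -2 * ll + design.shape[1] * np.log(n)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# loading-HMM LRLD detection


@dataclass
class HmmParams:
    """Two-state loading-HMM parameters.

    rho: state-switch intensity per cM; pi_in: stationary prior of the
    in-region state; posterior_threshold: call cutoff on the marginal
    posterior; merge_bp: regions closer than this are merged; scale_floor:
    lower bound on the inflated mixture component's scale.
    """

    rho: float = 1.0
    pi_in: float = 0.05
    posterior_threshold: float = 0.5
    merge_bp: int = 1_000_000
    scale_floor: float = 3.0
    min_cm_step: float = 1e-6

    def __post_init__(self):
        if not (0 < self.pi_in < 1):
            raise ValueError("pi_in must be in (0, 1)")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if not (0 < self.posterior_threshold < 1):
            raise ValueError("posterior_threshold must be in (0, 1)")


@dataclass
class LrldRegion:
    chrom: str
    start: int
    end: int
    pc: int
    peak_posterior: float
    iteration: int = 0


def fit_z2_mixture(z2: np.ndarray, scale_floor: float = 3.0,
                   max_iter: int = 200) -> dict:
    """Two-component scaled chi-square(1) mixture on squared loading Z-scores.

    Null component has scale fixed at 1; the inflated component's scale and
    the mixing weight are fitted by EM (scale floored).  Returns the
    per-observation posterior of the inflated component and the parameters;
    ``degenerate`` is set when EM collapses to a single component.
    """
    x = np.clip(np.asarray(z2, dtype=float), 1e-12, None)
    w = 0.05
    s = max(scale_floor, 5.0)
    f0 = stats.chi2.pdf(x, df=1)
    for _ in range(max_iter):
        f1 = stats.chi2.pdf(x / s, df=1) / s
        num = w * f1
        den = num + (1 - w) * f0
        r = num / np.where(den > 0, den, 1e-300)
        w_new = float(np.mean(r))
        sr = float(np.sum(r))
        s_new = max(float(np.sum(r * x) / sr) if sr > 0 else s, scale_floor)
        if abs(w_new - w) < 1e-8 and abs(s_new - s) < 1e-6:
            w, s = w_new, s_new
            break
        w, s = w_new, s_new
    f1 = stats.chi2.pdf(x / s, df=1) / s
    num = w * f1
    den = num + (1 - w) * f0
    post = num / np.where(den > 0, den, 1e-300)
    # evidence gate: the two-component fit must beat the pure null by a BIC
    # margin (2 extra parameters), else the track is declared inflation-free
    ll_null = float(np.sum(np.log(np.clip(f0, 1e-300, None))))
    ll_mix = float(np.sum(np.log(np.clip(den, 1e-300, None))))
    bic_gain = 2.0 * (ll_mix - ll_null) - 2.0 * np.log(x.size)
    degenerate = w < 1e-6 or w > 1 - 1e-6 or bic_gain <= 0
    return {"posterior": post, "weight": w, "scale": s,
            "degenerate": degenerate, "bic_gain": bic_gain}


def transition_matrices(cm_positions: np.ndarray, params: HmmParams) -> np.ndarray:
    """(m-1, 2, 2) transition matrices; state order (out, in).

    Between adjacent variants separated by d cM, the switch mass is
    1 - exp(-rho * d), split to balance the stationary prior:
    a(out->in) = pi_in * mass, a(in->out) = (1 - pi_in) * mass.
    """
    d = np.diff(np.asarray(cm_positions, dtype=float))
    d = np.maximum(d, params.min_cm_step)
    mass = 1.0 - np.exp(-params.rho * d)
    a01 = params.pi_in * mass
    a10 = (1.0 - params.pi_in) * mass
    T = np.empty((d.size, 2, 2))
    T[:, 0, 0] = 1 - a01
    T[:, 0, 1] = a01
    T[:, 1, 0] = a10
    T[:, 1, 1] = 1 - a10
    return T


def forward_backward(emissions: np.ndarray, T: np.ndarray,
                     initial: np.ndarray) -> np.ndarray:
    """Scaled forward-backward; returns (m, n_states) marginal posteriors.

    ``emissions[i, s]`` is the emission weight of state s at step i;
    ``T[i]`` the transition matrix from step i to i+1.
    """
    e = np.asarray(emissions, dtype=float)
    m, k = e.shape
    alpha = np.empty((m, k))
    scale = np.empty(m)
    a = initial * e[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for i in range(1, m):
        a = (alpha[i - 1] @ T[i - 1]) * e[i]
        scale[i] = a.sum()
        alpha[i] = a / scale[i]
    beta = np.empty((m, k))
    beta[-1] = 1.0
    for i in range(m - 2, -1, -1):
        b = T[i] @ (e[i + 1] * beta[i + 1])
        beta[i] = b / scale[i + 1]
    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def detect_lrld_hmm(
    loadings: np.ndarray,
    chroms,
    positions: np.ndarray,
    genetic_map: GeneticMap,
    params: HmmParams | None = None,
    pc: int = 0,
    min_chrom_variants: int = 100,
    iteration: int = 0,
) -> list[LrldRegion]:
    """HMM scan of one PC's loadings for long-range-LD regions.

    Z-scores are standardised over all variants on the PC; the mixture
    posterior of the squared Z forms the emission evidence (in-state emits
    e_i, out-state 1-e_i); transitions follow the genetic map.  Variants
    with marginal posterior above the threshold are grouped into runs,
    boundaries extended to the midpoint toward the neighbouring variant, and
    runs closer than the merge distance are merged.
    """
    params = params or HmmParams()
    load = np.asarray(loadings, dtype=float)
    z = (load - load.mean()) / load.std(ddof=0)
    z2 = np.clip(z**2, 1e-12, None)
    mix = fit_z2_mixture(z2, scale_floor=params.scale_floor)
    if mix["degenerate"]:
        return []
    # per-variant evidence: equal-prior posterior of the inflated component
    # (the mixing weight is deliberately left out — the in-region prior is
    # carried by the HMM's stationary distribution, not the emissions)
    f0 = stats.chi2.pdf(z2, df=1)
    f1 = stats.chi2.pdf(z2 / mix["scale"], df=1) / mix["scale"]
    evidence = np.clip(f1 / (f0 + f1), 1e-9, 1 - 1e-9)
    chroms = pd.Series(chroms).astype(str).to_numpy()
    positions = np.asarray(positions)
    regions: list[LrldRegion] = []
    initial = np.array([1 - params.pi_in, params.pi_in])
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        if sel.sum() < min_chrom_variants:
            continue
        pos = positions[sel]
        order = np.argsort(pos)
        pos = pos[order]
        e_in = evidence[sel][order]
        em = np.column_stack([1 - e_in, e_in])
        T = transition_matrices(genetic_map.interpolate(chrom, pos), params)
        post = forward_backward(em, T, initial)[:, 1]
        in_state = post > params.posterior_threshold
        regions.extend(
            _runs_to_regions(in_state, post, pos, chrom, pc, iteration, params))
    return regions


def _runs_to_regions(in_state, post, pos, chrom, pc, iteration, params):
    regions = []
    m = in_state.size
    i = 0
    while i < m:
        if not in_state[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and in_state[j + 1]:
            j += 1
        start = int(pos[i] if i == 0 else (pos[i] + pos[i - 1]) // 2)
        end = int(pos[j] if j == m - 1 else (pos[j] + pos[j + 1]) // 2)
        regions.append(LrldRegion(chrom=str(chrom), start=start, end=end, pc=pc,
                                  peak_posterior=float(post[i:j + 1].max()),
                                  iteration=iteration))
        i = j + 1
    return merge_regions(regions, params.merge_bp)


def merge_regions(regions: list[LrldRegion], merge_bp: int) -> list[LrldRegion]:
    """Merge same-chromosome regions closer than ``merge_bp``."""
    out: list[LrldRegion] = []
    for reg in sorted(regions, key=lambda r: (r.chrom, r.start)):
        if out and out[-1].chrom == reg.chrom and reg.start - out[-1].end < merge_bp:
            prev = out[-1]
            out[-1] = replace(prev, end=max(prev.end, reg.end),
                              peak_posterior=max(prev.peak_posterior,
                                                 reg.peak_posterior))
        else:
            out.append(reg)
    return out


def iterate_lrld_pca(
    calls: np.ndarray,
    variants: pd.DataFrame,
    labels,
    genetic_map: GeneticMap,
    pruned_idx: np.ndarray | None = None,
    params: HmmParams | None = None,
    n_pcs: int = 10,
    seed_exclusions: list[LrldRegion] | None = None,
    max_iterations: int = 10,
) -> tuple[PCAResult, list[LrldRegion], int]:
    """Iterative PCA / LRLD-scan loop.

    Each round: PCA on the current variant set; the number k of PCs
    informative for ``labels`` (BIC, multinomial); HMM scan of PCs 1..k+1
    (one beyond the informative set as a control); exclusion of variants in
    newly found regions.  Stops when a round finds nothing new, or at the
    iteration cap (with a warning).  Returns the final PCA, all regions
    (merged, disjoint), and the informative k of the final round.
    """
    params = params or HmmParams()
    idx = np.asarray(pruned_idx) if pruned_idx is not None \
        else np.arange(calls.shape[1])
    all_regions: list[LrldRegion] = list(seed_exclusions or [])
    if all_regions:
        idx = _exclude_regions(idx, variants, all_regions)
    pca = None
    k = 0
    for it in range(1, max_iterations + 1):
        pca = run_pca(calls, idx, n_pcs=n_pcs)
        k = select_informative_pcs(pca.scores, labels, "multinomial")["k"]
        scan_pcs = range(min(k + 1, pca.scores.shape[1]))
        new_regions: list[LrldRegion] = []
        chroms = variants["chrom"].to_numpy()[pca.variant_idx]
        pos = variants["pos"].to_numpy()[pca.variant_idx]
        for pc in scan_pcs:
            new_regions.extend(detect_lrld_hmm(
                pca.loadings[:, pc], chroms, pos, genetic_map, params,
                pc=pc, iteration=it))
        new_regions = [r for r in new_regions
                       if not _covered(r, all_regions)]
        if not new_regions:
            return pca, merge_regions(all_regions, params.merge_bp), k
        all_regions.extend(new_regions)
        all_regions = merge_regions(all_regions, params.merge_bp)
        idx = _exclude_regions(idx, variants, all_regions)
    warnings.warn(f"LRLD iteration cap ({max_iterations}) reached; partial result")
    return pca, merge_regions(all_regions, params.merge_bp), k


def _covered(region: LrldRegion, regions: list[LrldRegion]) -> bool:
    return any(r.chrom == region.chrom and r.start <= region.start
               and r.end >= region.end for r in regions)


def _exclude_regions(idx, variants, regions):
    chrom = variants["chrom"].astype(str).to_numpy()[idx]
    pos = variants["pos"].to_numpy()[idx]
    keep = np.ones(idx.size, dtype=bool)
    for r in regions:
        keep &= ~((chrom == r.chrom) & (pos >= r.start) & (pos <= r.end))
    return idx[keep]


# ---------------------------------------------------------------------------
# regional outliers & local PCA


def regional_outliers(
    scores: np.ndarray,
    region_ids,
    k: int,
    sd_cutoff: float = 3.0,
    min_region: int = 50,
    support_fraction: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Robust Mahalanobis ancestry outliers within each recruitment region.

    Location/scatter per region come from the minimum covariance determinant
    (75% support) on the first k PCs.  The squared-distance cutoff is the
    chi-square quantile with k df matching the two-sided 3-SD tail mass, so
    the flag fraction under a clean Gaussian region is ~0.27%.  Singular
    scatter falls back to a per-PC |Z| > 3 rule (logged in the output).
    """
    s = np.asarray(scores, dtype=float)[:, :max(k, 1)]
    regions = pd.Series(region_ids).astype(str).reset_index(drop=True)
    dim = s.shape[1]
    chi2_cut = stats.chi2.ppf(stats.chi2.cdf(sd_cutoff**2, df=1), df=dim)
    dist2 = np.full(len(regions), np.nan)
    flagged = np.zeros(len(regions), dtype=bool)
    method = np.array(["mcd"] * len(regions), dtype=object)
    for region, idx in regions.groupby(regions).groups.items():
        idx = np.asarray(list(idx))
        sub = s[idx]
        if idx.size < min_region:
            method[idx] = "region_too_small"
            continue
        try:
            mcd = MinCovDet(support_fraction=support_fraction,
                            random_state=seed).fit(sub)
            d2 = mcd.mahalanobis(sub)
        except Exception:
            mu = np.median(sub, axis=0)
            sd = stats.median_abs_deviation(sub, axis=0, scale="normal")
            sd[sd == 0] = np.inf
            z = (sub - mu) / sd
            d2 = np.max(z**2, axis=1)
            method[idx] = "per_pc_fallback"
            flagged[idx] = np.max(np.abs(z), axis=1) > sd_cutoff
            dist2[idx] = d2
            continue
        dist2[idx] = d2
        flagged[idx] = d2 > chi2_cut
    return pd.DataFrame({
        "region": regions, "dist2": dist2, "flagged": flagged, "method": method,
    })


def local_pca(
    calls: np.ndarray,
    region_mask: np.ndarray,
    center_coords: np.ndarray,
    variant_idx: np.ndarray | None = None,
    n_pcs: int = 10,
) -> dict:
    """Within-region PCA and the number of PCs informative for geography.

    ``center_coords`` is (n_region_samples, 2) latitude/longitude of each
    sample's assessment centre.  Regions with fewer than 2 distinct centres
    return k = 0.
    """
    sub = calls[np.asarray(region_mask, dtype=bool)]
    coords = np.asarray(center_coords, dtype=float)
    pca = run_pca(sub, variant_idx, n_pcs=n_pcs)
    if np.unique(coords, axis=0).shape[0] < 2:
        return {"pca": pca, "k": 0, "bics": []}
    sel = select_informative_pcs(pca.scores, coords, model="linear_2d")
    return {"pca": pca, "k": sel["k"], "bics": sel["bics"]}


# ---------------------------------------------------------------------------
# Fst


def weir_cockerham_fst(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
) -> float:
    """Two-population Weir-Cockerham theta (ratio-of-sums across variants).

    Variance-components estimator with r = 2 subpopulations; negative
    estimates are reported as computed.
    """
    ga = np.where(calls_a == MISSING, np.nan, calls_a).astype(float)
    gb = np.where(calls_b == MISSING, np.nan, calls_b).astype(float)
    n1 = np.sum(~np.isnan(ga), axis=0).astype(float)
    n2 = np.sum(~np.isnan(gb), axis=0).astype(float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore"):
        p1 = np.nanmean(ga, axis=0) / 2.0
        p2 = np.nanmean(gb, axis=0) / 2.0
        h1 = np.nanmean(ga == 1, axis=0)
        h2 = np.nanmean(gb == 1, axis=0)
    n1, n2, p1, p2, h1, h2 = (v[ok] for v in (n1, n2, p1, p2, h1, h2))
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = np.sum(a + b + c)
    return float(np.sum(a) / denom) if denom != 0 else np.nan


def fst_matrix(
    dataset: GenotypeDataset,
    region_ids=None,
    maf_min: float = 0.01,
    min_region: int = 20,
) -> pd.DataFrame:
    """Pairwise Weir-Cockerham Fst between recruitment regions.

    Symmetric with a zero diagonal; regions smaller than ``min_region``
    trigger a warning but are still estimated.
    """
    regions = pd.Series(
        region_ids if region_ids is not None else dataset.samples["region"]
    ).astype(str).reset_index(drop=True)
    levels = sorted(regions.unique())
    if len(levels) < 2:
        raise ValueError("Fst needs at least 2 regions")
    af = dataset.allele_frequencies()
    maf = np.minimum(af, 1 - af)
    keep = np.flatnonzero(dataset.autosomal_mask() & (maf > maf_min))
    mat = pd.DataFrame(0.0, index=levels, columns=levels)
    groups = {lev: np.flatnonzero((regions == lev).to_numpy()) for lev in levels}
    for lev, idx in groups.items():
        if idx.size < min_region:
            warnings.warn(f"region {lev} has only {idx.size} samples")
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            fst = weir_cockerham_fst(
                dataset.calls[np.ix_(groups[a], keep)],
                dataset.calls[np.ix_(groups[b], keep)],
            )
            mat.loc[a, b] = mat.loc[b, a] = fst
    return mat
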