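"""GWAS preparation: population-representative subset construction, the
effective minor-allele-count filter, ICD-10 case definition, a desk-scale
logistic association scan (a stand-in for the mixed-model software used at
biobank scale — labelled as such in the output), fixed-effect region
meta-analysis, and LD clumping of summary statistics.

Case over-ascertainment (nested case-control selections) biases analyses of
binary traits on the full genotyped set.  Because most samples were selected
for genotyping as whole storage boxes, restricting to samples whose source
box had at least 40% of its members genotyped removes the individually
cherry-picked cases and restores population-representative prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import logistic_scan
from .data import MISSING

BOX_FRACTION_THRESHOLD = 0.40
MAC_EFF_THRESHOLD = 20.0
MIN_CASES = 100
CLUMP_P1 = 5e-8
CLUMP_KB = 5000.0
CLUMP_R2 = 0.05
CLUMP_P2 = 0.05


def representative_subset(
    box_ids,
    box_fractions: dict,
    sample_ids=None,
    threshold: float = BOX_FRACTION_THRESHOLD,
) -> pd.DataFrame:
    """Samples whose source box had >= 40% of members selected for genotyping.

    Parameters
    ----------
    box_ids
        source-box id per genotyped sample (unmapped samples get NaN/None and
        are excluded with a warning flag in the output).
    box_fractions
        box id -> fraction of the box selected for genotyping.
    """
    boxes = pd.Series(box_ids).reset_index(drop=True)
    ids = pd.Series(sample_ids).reset_index(drop=True) if sample_ids is not None \
        else pd.Series(np.arange(len(boxes)))
    frac = boxes.map(lambda b: box_fractions.get(str(b),
                                                 box_fractions.get(b, np.nan)))
    unmapped = frac.isna()
    include = (frac >= threshold).fillna(False)
    return pd.DataFrame({
        "id": ids, "box": boxes, "box_fraction": frac,
        "in_subset": include, "unmapped": unmapped,
    })


def mac_eff_filter(
    maf,
    info,
    n_cases: int,
    n_controls: int,
    threshold: float = MAC_EFF_THRESHOLD,
) -> pd.DataFrame:
    """Effective minor-allele-count filter for a case-control scan.

    MAC_eff = 2 * MAF * info * N_eff with N_eff = 4 / (1/N_cases +
    1/N_controls); variants with MAC_eff below the threshold are dropped.
    Info values above 1 are clamped with a warning flag.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must both be positive")
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    info = np.atleast_1d(np.asarray(info, dtype=float))
    if (maf < 0).any() or (info < 0).any():
        raise ValueError("maf and info must be non-negative")
    clamped = info > 1.0
    info = np.minimum(info, 1.0)
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    mac_eff = 2.0 * maf * info * n_eff
    return pd.DataFrame({
        "maf": maf, "info": info, "n_eff": n_eff, "mac_eff": mac_eff,
        "keep": mac_eff >= threshold, "info_clamped": clamped,
    })


def case_definition(
    events: pd.DataFrame,
    subset_ids,
    all_ids,
    sex=None,
    sex_specific_codes: dict | None = None,
    min_cases: int = MIN_CASES,
) -> dict:
    """Case/control vectors per 3-character ICD-10 code.

    Cases are genotyped samples carrying the code; controls are non-case
    members of the population-representative subset.  Codes restricted to
    one sex (from ``sex_specific_codes``: code -> 'M'/'F') drop the other
    sex from both groups before the >= ``min_cases`` check.  Codes below the
    minimum are skipped (reported in ``skipped``).

    Returns {'phenotypes': {code: Series indexed by all_ids with 1/0/NaN},
    'skipped': [...]}.
    """
    all_ids = pd.Index(all_ids)
    subset = set(subset_ids)
    sex_map = pd.Series(sex, index=all_ids).astype(str).str.upper() \
        if sex is not None else None
    sex_specific_codes = sex_specific_codes or {}
    phenos = {}
    skipped = []
    codes = events["code"].astype(str).str[:3]
    for code in sorted(codes.unique()):
        case_ids = set(events.loc[codes == code, "id"]) & set(all_ids)
        pheno = pd.Series(np.nan, index=all_ids)
        controls = [s for s in all_ids if s in subset and s not in case_ids]
        pheno.loc[list(case_ids)] = 1.0
        pheno.loc[controls] = 0.0
        restrict = sex_specific_codes.get(code)
        if restrict and sex_map is not None:
            pheno[sex_map != restrict.upper()] = np.nan
        n_cases = int((pheno == 1).sum())
        if n_cases < min_cases:
            skipped.append((code, n_cases))
            continue
        phenos[code] = pheno
    return {"phenotypes": phenos, "skipped": skipped}


def association_scan(
    calls: np.ndarray,
    phenotype,
    covariates: pd.DataFrame,
    variant_info: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant logistic association scan with Firth fallback.

    This is a plain logistic-regression stand-in for biobank-scale
    mixed-model software; covariates should follow the standard recipe
    (array version, sex, age, age^2, region indicators, leading PCs).
    ``phenotype`` may contain NaN (samples excluded from the scan).

    Returns per-variant beta, se, p (Wald), counts and flags.
    """
    y = np.asarray(phenotype, dtype=float)
    keep = np.isfinite(y)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 phenotyped samples")
    y = y[keep]
    cov = covariates.reset_index(drop=True).loc[np.flatnonzero(keep)]
    C = np.column_stack([np.ones(keep.sum()), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    G = np.where(calls[keep] == MISSING, np.nan, calls[keep]).astype(float)
    res = logistic_scan(y, C, G)
    out = pd.DataFrame({
        "beta": res["beta"],
        "se": res["se"],
        "p": res["p_wald"],
        "n_cases": int(y.sum()),
        "n_controls": int((1 - y).sum()),
        "flag": res["flag"],
    })
    out.loc[out["flag"] == "monomorphic", ["beta", "se", "p"]] = np.nan
    if variant_info is not None:
        out = pd.concat([variant_info.reset_index(drop=True), out], axis=1)
    out.attrs["method"] = "logistic_firth_standin"
    return out


def genomic_control_lambda(pvalues) -> float:
    """Median chi-square inflation factor of a scan's p-values."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def region_stratified_meta(strata: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis over region strata.

    Each stratum DataFrame needs beta and se columns aligned on the same
    variants.  Returns pooled beta/se/p plus Cochran's Q, its p-value and
    I-squared; a single stratum passes through with a note.
    """
    if len(strata) == 0:
        raise ValueError("no strata supplied")
    if len(strata) == 1:
        out = strata[0][["beta", "se"]].copy()
        out["p"] = 2 * stats.norm.sf(np.abs(out["beta"] / out["se"]))
        out["q"] = 0.0
        out["q_p"] = 1.0
        out["i2"] = 0.0
        out["n_strata"] = 1
        out.attrs["note"] = "single stratum pass-through"
        return out
    betas = np.column_stack([s["beta"].to_numpy(dtype=float) for s in strata])
    ses = np.column_stack([s["se"].to_numpy(dtype=float) for s in strata])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / ses**2
    ok = np.isfinite(betas) & np.isfinite(w)
    w = np.where(ok, w, 0.0)
    bz = np.where(ok, betas, 0.0)
    wsum = w.sum(axis=1)
    pooled = np.where(wsum > 0, (w * bz).sum(axis=1) / wsum, np.nan)
    pooled_se = np.where(wsum > 0, 1.0 / np.sqrt(wsum), np.nan)
    q = np.nansum(w * (bz - pooled[:, None]) ** 2, axis=1)
    df = ok.sum(axis=1) - 1
    q_p = np.where(df > 0, stats.chi2.sf(q, np.maximum(df, 1)), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        i2 = np.clip((q - df) / np.where(q > 0, q, np.inf), 0, 1)
    return pd.DataFrame({
        "beta": pooled, "se": pooled_se,
        "p": 2 * stats.norm.sf(np.abs(pooled / pooled_se)),
        "q": q, "q_p": q_p, "i2": i2, "n_strata": ok.sum(axis=1),
    })


@dataclass
class ClumpParams:
    p1: float = CLUMP_P1
    kb: float = CLUMP_KB
    r2: float = CLUMP_R2
    p2: float = CLUMP_P2


def ld_clump(
    results: pd.DataFrame,
    ld_calls: np.ndarray | None = None,
    params: ClumpParams | None = None,
) -> pd.DataFrame:
    """Greedy LD clumping of association results into loci.

    Repeatedly takes the most significant unassigned variant with p <= p1 as
    a locus index, then assigns every unassigned variant within ``kb`` of it
    on the same chromosome with r-squared >= ``r2`` (computed from
    ``ld_calls``) and p <= p2 to that locus.  Indices missing from the LD
    source are clumped by distance only and flagged.

    ``results`` needs chrom, pos, p columns; row order must match the
    columns of ``ld_calls``.
    """
    params = params or ClumpParams()
    res = results.reset_index(drop=True)
    m = len(res)
    locus = np.full(m, -1)
    index_flag = np.zeros(m, dtype=bool)
    distance_only = np.zeros(m, dtype=bool)
    p = res["p"].to_numpy(dtype=float)
    chrom = res["chrom"].astype(str).to_numpy()
    pos = res["pos"].to_numpy(dtype=float)
    g = None
    if ld_calls is not None:
        g = np.where(ld_calls == MISSING, np.nan, ld_calls).astype(float)
    order = np.argsort(p, kind="stable")
    next_locus = 0
    for v in order:
        if locus[v] >= 0 or not np.isfinite(p[v]) or p[v] > params.p1:
            continue
        locus[v] = next_locus
        index_flag[v] = True
        near = (locus < 0) & (chrom == chrom[v]) & \
               (np.abs(pos - pos[v]) <= params.kb * 1000.0) & (p <= params.p2)
        cand = np.flatnonzero(near)
        if cand.size:
            if g is not None:
                r2 = _r2_with(g, v, cand)
                assign = cand[r2 >= params.r2]
            else:
                assign = cand
                distance_only[cand] = True
            locus[assign] = next_locus
        next_locus += 1
    out = res.copy()
    out["locus"] = locus
    out["is_index"] = index_flag
    out["distance_only"] = distance_only
    return out


def _r2_with(g: np.ndarray, v: int, cand: np.ndarray) -> np.ndarray:
    x = g[:, v]
    y = g[:, cand]
    ok = np.isfinite(x)[:, None] & np.isfinite(y)
    xm = np.where(ok, x[:, None], np.nan)
    ym = np.where(ok, y, np.nan)
    xc = xm - np.nanmean(xm, axis=0)
    yc = ym - np.nanmean(ym, axis=0)
    num = np.nansum(xc * yc, axis=0)
    den = np.sqrt(np.nansum(xc**2, axis=0) * np.nansum(yc**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(np.isfinite(r), r**2, 0.0)
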