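"""Variant-level QC: initial plate QC, plate/batch genotype-calling deviation
tests with empirically derived fail rules, region-stratified Hardy-Weinberg
testing, reference allele-frequency discordance, and duplicate-probeset
resolution.

The plate/batch tests regress plate (or batch) membership on genotype dosage
with recruitment region as covariate — a probeset whose calls shift on one
plate shows up as an association between dosage and that plate.  Fail rules
combine the resulting p-values with probeset clustering metrics (FLD, HetSO,
HomRO); borderline cases that the original workflow sent to manual
cluster-plot review are carried as ``review`` flags, never silently passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._logistic import logistic_scan, region_design
from .data import MISSING, GenotypeDataset

# initial (pre-clustering) QC thresholds
DQC_MIN = 0.82
QC_CALLRATE_MIN = 0.97
PLATE_MEAN_CALLRATE_MIN = 0.985
PLATE_PASS_RATE_FLAG = 0.95

# plate-effect fail rules
PLATE_P_HARD = 1e-10
PLATE_P_SOFT = 1e-4
PLATE_SOFT_MAX = 3          # fail when *more than* 3 plates below soft level
PLATE_P_METRIC = 1e-8
PLATE_P_REVIEW = 2e-5
FLD_BAD = 8.0
HETSO_BAD = 0.68
HOMRO_BAD = 3.7

# batch-effect fail rules (per array version)
BATCH_P_HARD = 1e-10
BATCH_P_SOFT = 1e-4
BATCH_SOFT_MAX = {1: 2, 2: 7}
BATCH_P_REVIEW = 1e-3
BATCH_FAIL_FRACTION = 0.10
BATCH_PASS_CALLRATE_MIN = 0.98

HWE_P_MIN = 1e-6
REF_MAF_MAX_DIFF = 0.2

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def initial_plate_qc(sample_metrics: pd.DataFrame, plate_ids) -> dict:
    """Initial sample/plate exclusions from pre-clustering quality metrics.

    Samples fail on DQC < 0.82 or QC call rate < 97%; plates whose remaining
    samples average a call rate < 98.5% are excluded outright; plates with a
    sample pass rate < 95% are flagged for review.

    Parameters
    ----------
    sample_metrics
        DataFrame with ``id``, ``dqc`` and ``qc_callrate`` columns.
    plate_ids
        plate assignment per row of ``sample_metrics``.

    Returns
    -------
    dict with ``excluded_samples``, ``excluded_plates``, ``flagged_plates``.
    """
    met = sample_metrics.reset_index(drop=True)
    plates = pd.Series(plate_ids).reset_index(drop=True)
    sample_fail = (met["dqc"] < DQC_MIN) | (met["qc_callrate"] < QC_CALLRATE_MIN)
    excluded_samples = met.loc[sample_fail, "id"].tolist()
    excluded_plates, flagged_plates = [], []
    for plate, idx in plates.groupby(plates).groups.items():
        members = met.loc[idx]
        keep = ~sample_fail.loc[idx]
        if keep.sum() == 0:
            flagged_plates.append(plate)  # empty after exclusions: review
            continue
        if members.loc[keep, "qc_callrate"].mean() < PLATE_MEAN_CALLRATE_MIN:
            excluded_plates.append(plate)
        if keep.mean() < PLATE_PASS_RATE_FLAG:
            flagged_plates.append(plate)
    return {
        "excluded_samples": excluded_samples,
        "excluded_plates": excluded_plates,
        "flagged_plates": flagged_plates,
    }


def plate_effect_test(
    calls: np.ndarray,
    plate_ids,
    region_ids,
    encoding: str = "dosage",
) -> pd.DataFrame:
    """Per-plate genotype-calling deviation p-values for every variant.

    Each plate in turn is treated as "case" with all other plates in the
    batch as controls; membership is regressed on genotype with recruitment
    region indicators as covariates and the genotype term tested by a
    likelihood-ratio test.  ``encoding="dosage"`` uses the 1-df allelic
    dosage; ``encoding="genotype"`` uses a 2-df genotype-class encoding
    (het + minor-hom indicators), which is the sensitive choice for het->hom
    miscall artifacts that barely move the dosage mean.  Monomorphic
    variants get no p-value and a ``monomorphic`` flag.

    Returns a long DataFrame: (plate, variant index, p, flag).
    """
    from ._logistic import genotype_class_scan

    plates = pd.Series(plate_ids).astype(str).reset_index(drop=True)
    if plates.nunique() < 2:
        raise ValueError("plate effect test needs at least 2 plates")
    if encoding not in ("dosage", "genotype"):
        raise ValueError(f"unknown encoding {encoding!r}")
    C = region_design(region_ids)
    G = np.where(calls == MISSING, np.nan, calls).astype(float)
    frames = []
    for plate in sorted(plates.unique()):
        y = (plates == plate).to_numpy(dtype=float)
        if encoding == "dosage":
            res = logistic_scan(y, C, G)
        else:
            res = genotype_class_scan(y, C, calls)
        frames.append(pd.DataFrame({
            "plate": plate,
            "variant": np.arange(calls.shape[1]),
            "p": res["p"],
            "flag": res["flag"],
        }))
    return pd.concat(frames, ignore_index=True)


def apply_plate_fail_rules(
    plate_pvalues: np.ndarray,
    cluster_metrics: dict | None = None,
) -> dict:
    """Fail/review decision for one probeset from its per-plate p-values.

    Fail iff min p < 1e-10, or more than 3 plates at p < 1e-4, or min
    p < 1e-8 with degraded clustering metrics (FLD < 8, HetSO < 0.68 and
    HomRO < 3.7).  Any plate at p < 2e-5 otherwise earns a ``review`` flag
    (the manual cluster-plot inspection tier).  Missing metrics inside the
    metric-dependent band also yield ``review`` rather than a silent pass.

    Parameters
    ----------
    plate_pvalues
        array of per-plate p-values (NaN allowed).
    cluster_metrics
        dict with ``fld``, ``hetso``, ``homro`` for the probeset's batch,
        or None when unavailable.
    """
    p = np.asarray(plate_pvalues, dtype=float)
    p = p[np.isfinite(p)]
    out = {"fail": False, "review": False, "reason": "", "min_p": np.nan,
           "n_soft": 0}
    if p.size == 0:
        return out
    out["min_p"] = float(p.min())
    out["n_soft"] = int((p < PLATE_P_SOFT).sum())
    if p.min() < PLATE_P_HARD:
        out.update(fail=True, reason="plate_p_lt_1e-10")
        return out
    if out["n_soft"] > PLATE_SOFT_MAX:
        out.update(fail=True, reason="gt3_plates_p_lt_1e-4")
        return out
    if p.min() < PLATE_P_METRIC:
        if cluster_metrics is None or any(
            k not in cluster_metrics or not np.isfinite(cluster_metrics[k])
            for k in ("fld", "hetso", "homro")
        ):
            out.update(review=True, reason="metrics_missing_in_band")
            return out
        if (cluster_metrics["fld"] < FLD_BAD
                and cluster_metrics["hetso"] < HETSO_BAD
                and cluster_metrics["homro"] < HOMRO_BAD):
            out.update(fail=True, reason="p_lt_1e-8_bad_metrics")
            return out
    if p.min() < PLATE_P_REVIEW:
        out.update(review=True, reason="manual_review_band")
    return out


def batch_effect_test(
    calls: np.ndarray,
    batch_ids,
    region_ids,
    unrelated_mask: np.ndarray,
    array_version: int = 2,
) -> pd.DataFrame:
    """Per-variant batch-effect decision on the unrelated subset.

    Same regression as the plate test, at batch level.  Fail iff any batch
    p < 1e-10, or the count of batches at p < 1e-4 exceeds the
    array-version-specific limit (2 for version 1, 7 for version 2).
    Batches at p < 1e-3 otherwise are flagged for review.

    Returns per-variant DataFrame: (min_p, n_soft, fail, review, flag).
    """
    if array_version not in BATCH_SOFT_MAX:
        raise ValueError(f"unknown array version {array_version!r}")
    mask = np.asarray(unrelated_mask, dtype=bool)
    batches = pd.Series(batch_ids).astype(str).reset_index(drop=True)[mask.tolist()]
    sub_calls = calls[mask]
    sub_regions = pd.Series(region_ids).reset_index(drop=True)[mask.tolist()]
    C = region_design(sub_regions)
    G = np.where(sub_calls == MISSING, np.nan, sub_calls).astype(float)
    m = calls.shape[1]
    pmat = []
    for batch in sorted(batches.unique()):
        y = (batches == batch).to_numpy(dtype=float)
        res = logistic_scan(y, C, G)
        pmat.append(res["p"].to_numpy())
    pmat = np.vstack(pmat)  # (n_batches, m)
    with np.errstate(invalid="ignore"):
        min_p = np.nanmin(pmat, axis=0)
        n_soft = np.nansum(pmat < BATCH_P_SOFT, axis=0).astype(int)
    fail, review = apply_batch_fail_rules(min_p, n_soft, array_version)
    return pd.DataFrame({
        "variant": np.arange(m),
        "min_p": min_p,
        "n_soft": n_soft,
        "fail": fail,
        "review": review,
    })


def apply_batch_fail_rules(min_p, n_soft, array_version: int):
    """Batch-level fail/review decision from summary p-value statistics.

    Fail iff min p < 1e-10 or more than the version-specific count of
    batches (2 for array version 1, 7 for version 2) sit below p < 1e-4;
    otherwise a min p < 1e-3 earns a review flag.
    """
    if array_version not in BATCH_SOFT_MAX:
        raise ValueError(f"unknown array version {array_version!r}")
    min_p = np.atleast_1d(np.asarray(min_p, dtype=float))
    n_soft = np.atleast_1d(np.asarray(n_soft))
    limit = BATCH_SOFT_MAX[array_version]
    with np.errstate(invalid="ignore"):
        fail = (min_p < BATCH_P_HARD) | (n_soft > limit)
        review = ~fail & (min_p < BATCH_P_REVIEW)
    return fail, review


def hwe_region_test(
    calls: np.ndarray,
    region_ids,
    sex=None,
    chromosome: str | None = None,
) -> pd.DataFrame:
    """Region-stratified Hardy-Weinberg test per variant.

    Within each region a 1-df goodness-of-fit chi-square is computed from the
    genotype counts; the summed statistic is referred to a chi-square with
    df = number of contributing regions (10 in the full design).  Regions
    with fewer than 2 genotyped samples, or monomorphic in the region,
    contribute nothing and reduce the df.  For chrX variants only females
    are counted.

    Returns per-variant DataFrame: (statistic, df, p, fail).
    """
    regions = pd.Series(region_ids).astype(str).reset_index(drop=True)
    g = calls
    if chromosome is not None and str(chromosome).upper() == "X":
        if sex is None:
            raise ValueError("sex required for chrX Hardy-Weinberg testing")
        fem = (pd.Series(sex).astype(str).str.upper() == "F").to_numpy()
        g = g[fem]
        regions = regions[fem.tolist()].reset_index(drop=True)
    m = g.shape[1]
    stat = np.zeros(m)
    df = np.zeros(m, dtype=int)
    for region in sorted(regions.unique()):
        sub = g[(regions == region).to_numpy()]
        n_aa = (sub == 2).sum(axis=0).astype(float)
        n_ab = (sub == 1).sum(axis=0).astype(float)
        n_bb = (sub == 0).sum(axis=0).astype(float)
        n = n_aa + n_ab + n_bb
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = (2 * n_aa + n_ab) / (2 * n)
        q_hat = 1 - p_hat
        contributes = (n >= 2) & (p_hat > 0) & (p_hat < 1)
        e_aa = n * p_hat**2
        e_ab = n * 2 * p_hat * q_hat
        e_bb = n * q_hat**2
        with np.errstate(invalid="ignore", divide="ignore"):
            chi = ((n_aa - e_aa) ** 2 / e_aa
                   + (n_ab - e_ab) ** 2 / e_ab
                   + (n_bb - e_bb) ** 2 / e_bb)
        stat += np.where(contributes, np.nan_to_num(chi), 0.0)
        df += contributes.astype(int)
    with np.errstate(invalid="ignore"):
        p = np.where(df > 0, stats.chi2.sf(stat, np.maximum(df, 1)), np.nan)
    fail = np.where(df > 0, p < HWE_P_MIN, False)
    return pd.DataFrame({"statistic": stat, "df": df, "p": p, "fail": fail})


def hwe_midp_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Mid-p exact Hardy-Weinberg test for one region (secondary report)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    parity = n_rare % 2
    hets = np.arange(parity, n_rare + 1, 2)
    logprob = np.array([
        _log_hwe_prob(n, n_rare, int(h)) for h in hets
    ])
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs = prob[hets == n_ab][0] if (n_ab % 2) == parity and n_ab <= n_rare else 0.0
    tail = prob[prob <= obs + 1e-12].sum()
    return float(min(1.0, tail - 0.5 * obs))


def _log_hwe_prob(n, n_rare, n_het):
    from scipy.special import gammaln
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    return (n_het * np.log(2)
            + gammaln(n + 1)
            - gammaln(n_het + 1) - gammaln(n_hom_rare + 1) - gammaln(n_hom_common + 1)
            - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1)))


def reference_maf_filter(
    dataset_variants: pd.DataFrame,
    dataset_afs: np.ndarray,
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Allele harmonisation and reference MAF-discordance filter.

    Variants are matched to the reference table on (chrom, pos) and alleles,
    directly or after strand complement.  Strand-ambiguous (A/T, C/G) pairs
    are matched without flipping only when both MAFs are below 0.4; otherwise
    they are dropped as ambiguous.  Matched variants whose minor-allele
    frequency differs from the reference by more than 0.2 are dropped.
    Variants absent from the reference are flagged ``no_reference`` and kept.

    Parameters
    ----------
    dataset_variants
        variant map with chrom, pos, allele1, allele2.
    dataset_afs
        counted-allele (allele1) frequency per variant.
    reference
        DataFrame with chrom, pos, a1, a2, af (af = frequency of a1).

    Returns per-variant DataFrame: (keep, flipped, flag, maf, ref_maf).
    """
    ref_index = {}
    for row in reference.itertuples(index=False):
        ref_index.setdefault((str(row.chrom), int(row.pos)), []).append(
            (str(row.a1).upper(), str(row.a2).upper(), float(row.af)))
    out = []
    for v, af in zip(dataset_variants.itertuples(index=False), dataset_afs):
        a1, a2 = str(v.allele1).upper(), str(v.allele2).upper()
        key = (str(v.chrom), int(v.pos))
        entries = ref_index.get(key)
        maf = min(af, 1 - af) if np.isfinite(af) else np.nan
        if not entries:
            out.append((True, False, "no_reference", maf, np.nan))
            continue
        if len(entries) > 1:
            out.append((False, False, "multiallelic", maf, np.nan))
            continue
        r1, r2, raf = entries[0]
        ambiguous = {a1, a2} in ({"A", "T"}, {"C", "G"})
        flipped = False
        if (a1, a2) == (r1, r2):
            ref_af = raf
        elif (a1, a2) == (r2, r1):
            ref_af = 1 - raf
        else:
            c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
            if (c1, c2) == (r1, r2):
                ref_af, flipped = raf, True
            elif (c1, c2) == (r2, r1):
                ref_af, flipped = 1 - raf, True
            else:
                out.append((False, False, "allele_mismatch", maf, np.nan))
                continue
        ref_maf = min(ref_af, 1 - ref_af)
        if ambiguous and not (maf < 0.4 and ref_maf < 0.4):
            out.append((False, False, "ambiguous_strand", maf, ref_maf))
            continue
        if abs(maf - ref_maf) > REF_MAF_MAX_DIFF:
            out.append((False, flipped, "refmaf_discordant", maf, ref_maf))
            continue
        out.append((True, flipped, "", maf, ref_maf))
    return pd.DataFrame(
        out, columns=["keep", "flipped", "flag", "maf", "ref_maf"])


def resolve_duplicate_probesets(probesets: pd.DataFrame) -> pd.DataFrame:
    """Keep the best probeset per assayed variant.

    ``probesets`` needs columns ``variant``, ``probeset``, ``call_rate``.
    Per variant, the probeset with the highest call rate is retained; exact
    ties break to the lexicographically first probeset id (tie logged).
    Returns the input with added boolean ``keep`` and ``tie`` columns.
    """
    df = probesets.copy()
    df["keep"] = False
    df["tie"] = False
    for _, grp in df.groupby("variant"):
        best_rate = grp["call_rate"].max()
        best = grp[grp["call_rate"] == best_rate].sort_values("probeset")
        df.loc[best.index[0], "keep"] = True
        if len(best) > 1:
            df.loc[grp.index, "tie"] = True
    return df


@dataclass
class VariantQCReport:
    """Per-variant exclusion ledger; one primary status plus the statistic
    that triggered it, mirroring the accounting of the release tables."""

    table: pd.DataFrame
    rules_fired: list = field(default_factory=list)

    def counts(self) -> pd.Series:
        return self.table["status"].value_counts()

    def passing(self) -> np.ndarray:
        return (self.table["status"] == "pass").to_numpy()


STATUS_PRIORITY = [
    "fail_initial", "fail_plate", "fail_batch", "fail_hwe", "fail_refmaf",
    "fail_callrate", "fail_duplicate",
]


def compile_variant_report(
    dataset: GenotypeDataset,
    plate_decisions: pd.DataFrame | None = None,
    batch_decisions: pd.DataFrame | None = None,
    hwe: pd.DataFrame | None = None,
    refmaf: pd.DataFrame | None = None,
    duplicates: pd.DataFrame | None = None,
    callrate_min: float = BATCH_PASS_CALLRATE_MIN,
) -> VariantQCReport:
    """Consolidate stage outputs into one per-variant status table.

    Statuses are assigned in pipeline order (plate, batch, HWE, reference
    MAF, call rate, duplicate probeset); the first failing stage becomes the
    primary status and its statistic is recorded as evidence.  The function
    is idempotent: re-running on the same inputs reproduces the table.
    """
    m = dataset.n_variants
    status = np.array(["pass"] * m, dtype=object)
    evidence = np.array([""] * m, dtype=object)
    review = np.zeros(m, dtype=bool)

    def set_fail(mask, label, ev):
        fresh = mask & (status == "pass")
        status[fresh] = label
        evidence[fresh] = ev[fresh] if isinstance(ev, np.ndarray) else ev

    if plate_decisions is not None:
        fail = plate_decisions["fail"].to_numpy()
        ev = np.array([f"min_plate_p={x:.3g}" for x in plate_decisions["min_p"]],
                      dtype=object)
        set_fail(fail, "fail_plate", ev)
        review |= plate_decisions["review"].to_numpy()
    if batch_decisions is not None:
        fail = batch_decisions["fail"].to_numpy()
        ev = np.array([f"min_batch_p={x:.3g}" for x in batch_decisions["min_p"]],
                      dtype=object)
        set_fail(fail, "fail_batch", ev)
        review |= batch_decisions["review"].to_numpy()
    if hwe is not None:
        fail = hwe["fail"].to_numpy()
        ev = np.array([f"hwe_stat={s:.2f},p={x:.3g}" for s, x in
                       zip(hwe["statistic"], hwe["p"])], dtype=object)
        set_fail(fail, "fail_hwe", ev)
    if refmaf is not None:
        fail = (~refmaf["keep"]).to_numpy()
        ev = np.array([f"flag={f},maf={a:.3f},ref={b:.3f}" for f, a, b in
                       zip(refmaf["flag"], refmaf["maf"].fillna(-1),
                           refmaf["ref_maf"].fillna(-1))], dtype=object)
        set_fail(fail, "fail_refmaf", ev)
    cr = dataset.call_rate(axis=0)
    set_fail(cr < callrate_min, "fail_callrate",
             np.array([f"call_rate={x:.4f}" for x in cr], dtype=object))
    if duplicates is not None:
        fail = (~duplicates["keep"]).to_numpy()
        set_fail(fail, "fail_duplicate", "duplicate_probeset_lower_call_rate")

    table = pd.DataFrame({
        "id": dataset.variants["id"],
        "status": status,
        "evidence": evidence,
        "review": review,
        "call_rate": cr,
        "maf": np.minimum(dataset.allele_frequencies(),
                          1 - dataset.allele_frequencies()),
    })
    return VariantQCReport(table=table)
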