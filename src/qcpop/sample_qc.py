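"""Sample-level QC: call rate, region-standardised heterozygosity with the
runs-of-homozygosity rescue rule, sex inference and chromosome-X aneuploidy
karyotyping from intensity summaries, plate-orientation error tracing,
ancestry outliers, duplicate discovery, and the consolidated exclusion
ledger.

Heterozygosity shows a strong north-south gradient across recruitment
regions, so outlier screening is always region-standardised.  Samples with
low heterozygosity are retained when extensive runs of homozygosity explain
it (consanguinity rather than assay failure); high heterozygosity (possible
contamination / DNA mixture) is excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .data import MISSING, GenotypeDataset
from . import relatedness

HET_Z_HIGH = 3.0
HET_Z_LOW = -3.0
ROH_Z_RESCUE = 2.0
MIN_REGION_SIZE = 20
CALLRATE_MIN = 0.95
ANCESTRY_SD = 10.0
ANCESTRY_N_PCS = 10
DUPLICATE_PI_HAT = 0.95
XXY_F_MAX = 0.8
LRR_SCREEN_SD = 3.0
BAF_DEV_MIN = 0.08
MIN_BAF_PROBES = 30


def heterozygosity_outliers(het_fraction, region_ids,
                            min_region: int = MIN_REGION_SIZE) -> pd.DataFrame:
    """Region-standardised heterozygosity Z-scores and high-het exclusions.

    Z is standardised within recruitment region; samples with Z > +3 are
    excluded (contamination signature).  Regions smaller than ``min_region``
    yield no Z-scores (flagged, not excluded).
    """
    het = pd.Series(np.asarray(het_fraction, dtype=float))
    regions = pd.Series(region_ids).astype(str).reset_index(drop=True)
    z = pd.Series(np.nan, index=het.index)
    small_region = pd.Series(False, index=het.index)
    for region, idx in regions.groupby(regions).groups.items():
        vals = het.loc[idx]
        if len(idx) < min_region:
            small_region.loc[idx] = True
            continue
        sd = vals.std(ddof=1)
        if sd <= 1e-9 * max(abs(vals.mean()), 1.0):
            z.loc[idx] = 0.0
        else:
            z.loc[idx] = (vals - vals.mean()) / sd
    return pd.DataFrame({
        "het": het,
        "region": regions,
        "het_z": z,
        "fail_het_high": z > HET_Z_HIGH,
        "small_region": small_region,
    })


def low_het_roh_rule(het_z, roh_kb, region_ids) -> pd.DataFrame:
    """Exclude low-heterozygosity samples not explained by autozygosity.

    A sample fails iff het Z < -3 *and* its region-standardised total-ROH
    Z < 2; low heterozygosity with correspondingly extensive runs of
    homozygosity is retained as consanguinity.  Missing ROH totals on a
    low-het sample yield a ``review`` flag.
    """
    hz = pd.Series(np.asarray(het_z, dtype=float))
    roh = pd.Series(np.asarray(roh_kb, dtype=float))
    regions = pd.Series(region_ids).astype(str).reset_index(drop=True)
    roh_z = pd.Series(np.nan, index=roh.index)
    for region, idx in regions.groupby(regions).groups.items():
        vals = roh.loc[idx]
        sd = vals.std(ddof=1)
        roh_z.loc[idx] = (vals - vals.mean()) / sd if sd and sd > 0 else 0.0
    low = hz < HET_Z_LOW
    fail = low & (roh_z < ROH_Z_RESCUE)
    review = low & roh.isna()
    fail &= ~review
    return pd.DataFrame({
        "het_z": hz, "roh_z": roh_z,
        "fail_hom_low": fail.fillna(False),
        "review": review,
        "consanguineous": (low & (roh_z >= ROH_Z_RESCUE)).fillna(False),
    })


@dataclass
class RohParams:
    """Sliding-window run-of-homozygosity caller parameters (kb units)."""

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    min_snps: int = 50
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_chrom_variants: int = 50


def detect_roh(dataset: GenotypeDataset, params: RohParams | None = None) -> tuple:
    """Runs of homozygosity per sample over sorted autosomal variants.

    A window of ``window_snps`` consecutive variants is homozygous-compatible
    when it contains at most ``window_max_het`` heterozygous and
    ``window_max_missing`` missing calls; maximal stretches of variants all
    of whose covering windows are compatible become candidate segments, kept
    when they span at least ``min_length_kb`` and ``min_snps`` variants with
    no inter-variant gap above ``max_gap_kb``.

    Returns ``(segments, totals)``: a DataFrame (sample, chrom, start, end,
    n_snps, length_kb) and a per-sample total-kb Series aligned with the
    manifest.
    """
    params = params or RohParams()
    auto = dataset.autosomal_mask()
    segs = []
    totals = np.zeros(dataset.n_samples)
    variants = dataset.variants
    for chrom in variants.loc[auto, "chrom"].unique():
        sel = ((variants["chrom"] == chrom).to_numpy()) & auto
        pos = variants.loc[sel, "pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        calls = dataset.calls[:, np.flatnonzero(sel)[order]]
        if pos.size < params.min_chrom_variants:
            continue
        for i in range(dataset.n_samples):
            for s, e in _roh_runs(calls[i], pos, params):
                length_kb = (pos[e - 1] - pos[s]) / 1000.0
                segs.append((dataset.samples.at[i, "id"], chrom,
                             int(pos[s]), int(pos[e - 1]), e - s, length_kb))
                totals[i] += length_kb
    seg_df = pd.DataFrame(
        segs, columns=["sample", "chrom", "start", "end", "n_snps", "length_kb"])
    return seg_df, pd.Series(totals, index=dataset.samples["id"].to_numpy())


def _roh_runs(g: np.ndarray, pos: np.ndarray, params: RohParams):
    """Candidate homozygous runs for one sample on one chromosome."""
    m = g.size
    w = min(params.window_snps, m)
    het = (g == 1).astype(int)
    mis = (g == MISSING).astype(int)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - w + 1
    if n_win <= 0:
        return
    win_ok = ((chet[w:] - chet[:-w]) <= params.window_max_het) & \
             ((cmis[w:] - cmis[:-w]) <= params.window_max_missing)
    # variant i is ROH-compatible if some covering window passes
    ok = np.zeros(m, dtype=bool)
    cwin = np.concatenate([[0], np.cumsum(win_ok.astype(int))])
    for i in range(m):
        lo = max(0, i - w + 1)
        hi = min(i, n_win - 1)
        if hi >= lo and (cwin[hi + 1] - cwin[lo]) > 0:
            ok[i] = True
    # heterozygous calls can never sit inside a run boundary decision
    ok &= g != 1
    # split compatible stretches at large physical gaps
    i = 0
    while i < m:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and ok[j + 1] and (pos[j + 1] - pos[j]) <= params.max_gap_kb * 1000:
            j += 1
        n_snps = j - i + 1
        if n_snps >= params.min_snps and (pos[j] - pos[i]) >= params.min_length_kb * 1000:
            yield i, j + 1
        i = j + 1


@dataclass
class KaryotypeCall:
    sample: str
    call: str  # XX, XY, XO, XO_mosaic, XXX, XXY_like, X_structural, sex_mismatch, unresolved
    evidence: dict = field(default_factory=dict)


def infer_sex(metrics: pd.DataFrame, reported_sex) -> list[KaryotypeCall]:
    """Genetic sex from chrX heterozygosity F and chrY/chrX intensity ratio.

    A 2-component Gaussian mixture on (F, ratio) learns the male and female
    clusters (male: F near 1, high ratio); assignment thresholds are the
    cluster posteriors rather than fixed cutoffs.  Reported-sex mismatches
    are flagged; reported males with non-negligible chrX heterozygosity
    (F < 0.8) and depressed ratio are called XXY-like.
    """
    f = metrics["chrx_f"].to_numpy(dtype=float)
    ratio = metrics["y_x_ratio"].to_numpy(dtype=float)
    ids = metrics["id"].to_numpy()
    reported = pd.Series(reported_sex).astype(str).str.upper().to_numpy()
    pts = np.column_stack([f, ratio])
    finite = np.isfinite(pts).all(axis=1)
    calls: list[KaryotypeCall] = [None] * len(ids)

    gm = GaussianMixture(n_components=2, covariance_type="full", random_state=0,
                         n_init=3)
    labels = np.full(len(ids), -1)
    if finite.sum() >= 4:
        gm.fit(pts[finite])
        male_comp = int(np.argmax(gm.means_[:, 0]))  # higher F cluster = male
        labels[finite] = (gm.predict(pts[finite]) == male_comp).astype(int)
    male_ratio_mean = np.nanmean(ratio[labels == 1]) if (labels == 1).any() else np.nan

    for k, sid in enumerate(ids):
        ev = {"f": f[k], "ratio": ratio[k], "reported": reported[k]}
        if not finite[k]:
            calls[k] = KaryotypeCall(sid, "unresolved", ev)
            continue
        genetic = "M" if labels[k] == 1 else "F"
        if reported[k] == "M" and genetic == "M" and f[k] < XXY_F_MAX \
                and np.isfinite(male_ratio_mean) and ratio[k] < male_ratio_mean * 0.8:
            calls[k] = KaryotypeCall(sid, "XXY_like", ev)
        elif reported[k] == "M" and genetic == "F" and f[k] < XXY_F_MAX \
                and ratio[k] > np.nanmean(ratio[labels == 0]) + 3 * np.nanstd(ratio[labels == 0]):
            calls[k] = KaryotypeCall(sid, "XXY_like", ev)
        elif genetic != reported[k]:
            calls[k] = KaryotypeCall(sid, "sex_mismatch", ev)
        else:
            calls[k] = KaryotypeCall(sid, "XY" if genetic == "M" else "XX", ev)
    return calls


def classify_x_aneuploidy(
    metrics: pd.DataFrame,
    baf: dict,
    reported_sex,
) -> list[KaryotypeCall]:
    """ChrX aneuploidy karyotyping from mean LRR and BAF het-band structure.

    Screening: female-manifest samples with |LRR Z| > 3 (standardised over
    females).  Low LRR with no heterozygous BAF band is XO (Turner); low LRR
    with the het band displaced from 0.5 is mosaic XO; high LRR with het
    bands near 1/3 and 2/3 is XXX.  Samples with too few informative BAF
    probes are unresolved.
    """
    reported = pd.Series(reported_sex).astype(str).str.upper().to_numpy()
    fem = reported == "F"
    lrr = metrics["chrx_lrr_mean"].to_numpy(dtype=float)
    # robust location/scale over females: planted aneuploids would otherwise
    # inflate the screening SD in a small cohort
    mu = np.nanmedian(lrr[fem])
    sd = stats.median_abs_deviation(lrr[fem], scale="normal", nan_policy="omit")
    z = (lrr - mu) / sd if sd > 0 else np.zeros_like(lrr)
    out = []
    for k, sid in enumerate(metrics["id"]):
        if not fem[k]:
            continue
        ev = {"lrr": lrr[k], "lrr_z": z[k]}
        if abs(z[k]) <= LRR_SCREEN_SD:
            continue  # screen not triggered: no call
        vals = np.asarray(baf.get(sid, []), dtype=float)
        # het-informative BAF values (away from the homozygote rails)
        het_vals = vals[(vals > 0.1) & (vals < 0.9)] if vals.size else vals
        if z[k] < 0:
            if het_vals.size == 0:
                out.append(KaryotypeCall(sid, "XO", ev))
                continue
            if het_vals.size < MIN_BAF_PROBES:
                out.append(KaryotypeCall(sid, "unresolved", ev))
                continue
            dev = np.median(np.abs(het_vals - 0.5))
            ev["baf_dev"] = dev
            if dev > BAF_DEV_MIN:
                out.append(KaryotypeCall(sid, "XO_mosaic", ev))
            else:
                out.append(KaryotypeCall(sid, "X_structural", ev))
        else:
            if het_vals.size < MIN_BAF_PROBES:
                out.append(KaryotypeCall(sid, "unresolved", ev))
                continue
            dev = np.median(np.abs(het_vals - 0.5))
            ev["baf_dev"] = dev
            # two-mode fit: closer to (1/3, 2/3) than to 0.5?
            d_third = np.mean(np.minimum(np.abs(het_vals - 1 / 3),
                                         np.abs(het_vals - 2 / 3)))
            d_half = np.mean(np.abs(het_vals - 0.5))
            if dev > BAF_DEV_MIN and d_third < d_half:
                out.append(KaryotypeCall(sid, "XXX", ev))
            else:
                out.append(KaryotypeCall(sid, "X_structural", ev))
    return out


def detect_plate_orientation_errors(
    layout: pd.DataFrame,
    n_rows: int = 8,
    n_cols: int = 12,
) -> dict:
    """Classify sex-mismatch clusters per plate as 180-degree rotations.

    ``layout`` needs columns plate, well, reported_sex, inferred_sex.  For a
    plate with mismatches, reported sexes are permuted by the 180-degree well
    map (row r, col c) -> (R+1-r, C+1-c); the plate is ``rotated_180`` iff
    the rotation removes *all* mismatches and the identity layout had at
    least 2.  Plates with unexplained mismatches are ``unresolved`` (the
    whole block is then excluded downstream); clean plates are ``ok``.
    """
    results = {}
    for plate, grp in layout.groupby("plate"):
        wells = grp["well"].astype(str)
        rows = wells.str[0].map({chr(65 + i): i for i in range(n_rows)})
        cols = wells.str[1:].astype(int) - 1
        rep = grp["reported_sex"].astype(str).str.upper().to_numpy()
        inf = grp["inferred_sex"].astype(str).str.upper().to_numpy()
        informative = np.isin(inf, ["M", "F"])
        mism = int(((rep != inf) & informative).sum())
        if mism == 0:
            results[plate] = "ok"
            continue
        # reported sex found at the 180-degree-rotated position
        pos = {(r, c): s for r, c, s in zip(rows, cols, rep)}
        rot_rep = np.array([
            pos.get((n_rows - 1 - r, n_cols - 1 - c), "NA")
            for r, c in zip(rows, cols)
        ])
        rot_mism = int(((rot_rep != inf) & informative & (rot_rep != "NA")).sum())
        if mism >= 2 and rot_mism == 0:
            results[plate] = "rotated_180"
        else:
            results[plate] = "unresolved"
    return results


def ancestry_outliers(
    scores: np.ndarray,
    n_pcs: int = ANCESTRY_N_PCS,
    sd_cutoff: float = ANCESTRY_SD,
) -> pd.DataFrame:
    """Flag samples far from the cohort mean on reference-projected PCs.

    ``scores`` are cohort samples projected onto reference-panel principal
    components; a sample is flagged when it lies more than ``sd_cutoff``
    standard deviations from the cohort-wide mean on any of the first
    ``n_pcs`` PCs.
    """
    s = np.asarray(scores, dtype=float)[:, :n_pcs]
    mu = s.mean(axis=0)
    sd = s.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (s - mu) / sd
    worst = np.max(np.abs(z), axis=1)
    return pd.DataFrame({"max_abs_z": worst, "fail_ancestry": worst > sd_cutoff})


def find_duplicates(
    dataset: GenotypeDataset,
    n_thin: int = 10_000,
    maf_min: float = 0.05,
    expected_pairs: list | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Duplicate / monozygotic-twin discovery on a thinned variant set.

    Computes pairwise PI_HAT on up to ``n_thin`` autosomal variants with
    MAF > ``maf_min`` and reports pairs above 0.95.  Expected duplicates
    (from the plate manifest) are confirmed; per pair the copy with the
    lower call rate is marked for exclusion.  An expected duplicate that is
    *not* recovered is reported with ``status='missing_expected'`` — a
    plate-tracking alert.
    """
    rng = np.random.default_rng(seed)
    af = dataset.allele_frequencies()
    maf = np.minimum(af, 1 - af)
    cand = np.flatnonzero(dataset.autosomal_mask() & (maf > maf_min))
    if cand.size > n_thin:
        cand = np.sort(rng.choice(cand, size=n_thin, replace=False))
    ds = dataset.subset(variant_idx=cand)
    ids = ds.samples["id"].to_numpy()
    call_rate = ds.call_rate(axis=1)
    table = relatedness.pairwise_ibd_table(ds, by_region=False, min_overlap=100)
    dup = table[table["pi_hat"] > DUPLICATE_PI_HAT].copy()
    expected = {frozenset(p) for p in (expected_pairs or [])}
    cr = dict(zip(ids, call_rate))
    rows = []
    found = set()
    for r in dup.itertuples(index=False):
        key = frozenset((r.i, r.j))
        found.add(key)
        exclude = r.i if cr.get(r.i, 1) < cr.get(r.j, 1) else r.j
        rows.append((r.i, r.j, r.pi_hat,
                     "expected" if key in expected else "unexpected", exclude))
    for key in expected - found:
        a, b = sorted(key)
        rows.append((a, b, np.nan, "missing_expected", ""))
    return pd.DataFrame(
        rows, columns=["i", "j", "pi_hat", "status", "exclude"])


STATUS_ORDER = [
    "fail_initial", "fail_callrate", "fail_het_high", "fail_hom_low",
    "fail_sex_mismatch", "fail_linkage", "fail_aneuploidy", "fail_ancestry",
    "fail_consent",
]

ANEUPLOID_CALLS = {"XO", "XO_mosaic", "XXX", "XXY_like"}


def compile_sample_report(
    sample_ids,
    flags: dict,
) -> pd.DataFrame:
    """Consolidate per-stage exclusion flags into the sample QC ledger.

    ``flags`` maps status name (see :data:`STATUS_ORDER`) to an iterable of
    failing sample ids.  Each sample receives one primary status (first
    failing category in pipeline order) while every triggered flag is kept
    as evidence — samples can and do fail on more than one criterion.
    """
    ids = list(sample_ids)
    flag_sets = {k: set(v) for k, v in flags.items()}
    unknown = set(flag_sets) - set(STATUS_ORDER)
    if unknown:
        raise ValueError(f"unknown status categories: {sorted(unknown)}")
    rows = []
    for sid in ids:
        hit = [k for k in STATUS_ORDER if sid in flag_sets.get(k, ())]
        rows.append((sid, hit[0] if hit else "pass", ";".join(hit)))
    table = pd.DataFrame(rows, columns=["id", "status", "evidence_flags"])
    return table
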