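import numpy as np
import pandas as pd
import pytest

from qcpop.data import MISSING, GenotypeDataset
from qcpop.sample_qc import (
    RohParams,
    ancestry_outliers,
    classify_x_aneuploidy,
    compile_sample_report,
    detect_plate_orientation_errors,
    detect_roh,
    find_duplicates,
    heterozygosity_outliers,
    infer_sex,
    low_het_roh_rule,
)
from qcpop.simulate import (
    GeneticMap,
    PedigreeSpec,
    SimConfig,
    drop_gametes,
    sample_haplotypes,
    simulate_cohort,
)


class TestHeterozygosityOutliers:
    def test_identical_het_all_zero_z(self):
        out = heterozygosity_outliers([0.3] * 30, ["r"] * 30)
        assert (out["het_z"].abs() < 1e-12).all()
        assert not out["fail_het_high"].any()

    def test_region_specific_standardisation(self):
        # sample at +3.5 SD within its region but unremarkable globally
        rng = np.random.default_rng(0)
        north = rng.normal(0.32, 0.004, 100)
        south = rng.normal(0.26, 0.004, 100)
        south[0] = 0.26 + 3.5 * south.std(ddof=1) * 1.02
        het = np.concatenate([north, south])
        regions = ["n"] * 100 + ["s"] * 100
        out = heterozygosity_outliers(het, regions)
        assert out["fail_het_high"][100]
        global_z = (het[100] - het.mean()) / het.std(ddof=1)
        assert global_z < 3  # would not be caught globally

    def test_contaminated_sample_flagged(self):
        # 1:1 two-person DNA mixture inflates heterozygosity ~1.5x
        rng = np.random.default_rng(1)
        flagged = 0
        for rep in range(50):
            het = rng.normal(0.30, 0.005, 60)
            het[0] = 0.30 * 1.5
            out = heterozygosity_outliers(het, ["r"] * 60)
            flagged += bool(out["fail_het_high"][0])
        assert flagged == 50

    def test_small_region_yields_no_z(self):
        out = heterozygosity_outliers([0.2, 0.9], ["r", "r"])
        assert out["het_z"].isna().all()
        assert out["small_region"].all()
        assert not out["fail_het_high"].any()


class TestLowHetRohRule:
    def test_consanguineous_sample_retained(self):
        # low het but extensive ROH (region ROH-Z far above 2): rescued
        hz = [-3.5] + [0.0] * 20
        roh = [5000.0] + list(np.linspace(90, 110, 20))
        out = low_het_roh_rule(hz, roh, ["r"] * 21)
        assert not out["fail_hom_low"][0]
        assert out["consanguineous"][0]

    def test_low_het_without_roh_excluded(self):
        hz = [-3.5] + [0.0] * 20
        roh = [100.0] + list(np.linspace(90, 110, 20))
        out = low_het_roh_rule(hz, roh, ["r"] * 21)
        assert out["fail_hom_low"][0]

    def test_moderate_het_retained_regardless(self):
        out = low_het_roh_rule([-1.0, 0.0], [0.0, 0.0], ["r", "r"])
        assert not out["fail_hom_low"].any()

    def test_missing_roh_flagged_for_review(self):
        out = low_het_roh_rule([-3.5, 0.0], [np.nan, 10.0], ["r", "r"])
        assert out["review"][0]
        assert not out["fail_hom_low"][0]


def _roh_brute_force(g, pos, params):
    """Independent quadratic re-derivation of the windowed ROH definition."""
    m = g.size
    w = min(params.window_snps, m)
    ok = np.zeros(m, dtype=bool)
    for i in range(m):
        if g[i] == 1:
            continue
        for s in range(max(0, i - w + 1), min(i, m - w) + 1):
            win = g[s:s + w]
            if (win == 1).sum() <= params.window_max_het and \
               (win == MISSING).sum() <= params.window_max_missing:
                ok[i] = True
                break
    total = 0.0
    i = 0
    while i < m:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and ok[j + 1] and \
                (pos[j + 1] - pos[j]) <= params.max_gap_kb * 1000:
            j += 1
        if (j - i + 1) >= params.min_snps and \
                (pos[j] - pos[i]) >= params.min_length_kb * 1000:
            total += (pos[j] - pos[i]) / 1000.0
        i = j + 1
    return total


def _dataset(calls, pos, chrom="1"):
    m = calls.shape[1]
    variants = pd.DataFrame({"id": [f"v{i}" for i in range(m)], "chrom": chrom,
                             "pos": pos, "allele1": "A", "allele2": "G"})
    samples = pd.DataFrame({"id": [f"s{i}" for i in range(calls.shape[0])],
                            "sex": "F", "region": "r"})
    return GenotypeDataset(calls, variants, samples)


class TestDetectRoh:
    def test_fully_heterozygous_sample_has_no_roh(self):
        pos = np.arange(1, 3001) * 20_000
        calls = np.ones((1, 3000), dtype=np.int8)
        segs, tot = detect_roh(_dataset(calls, pos))
        assert len(segs) == 0 and tot.iloc[0] == 0

    def test_planted_segment_recovered_with_tight_boundaries(self):
        rng = np.random.default_rng(2)
        m = 2000
        pos = np.sort(rng.choice(60_000_000, m, replace=False))
        freqs = rng.uniform(0.35, 0.65, m)
        calls = rng.binomial(2, freqs, (1, m)).astype(np.int8)
        seg = (pos >= 20e6) & (pos <= 25e6)
        calls[0, seg] = np.where(rng.random(seg.sum()) < freqs[seg], 2, 0)
        segs, tot = detect_roh(_dataset(calls, pos))
        assert len(segs) >= 1
        spacing = 60e6 / m
        best = segs.iloc[segs["length_kb"].idxmax()]
        assert abs(best["start"] - 20e6) < 5 * spacing
        assert abs(best["end"] - 25e6) < 5 * spacing

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        params = RohParams(window_snps=20, min_snps=20, min_length_kb=500,
                           min_chrom_variants=30)
        for rep in range(5):
            m = 400
            pos = np.sort(rng.choice(30_000_000, m, replace=False))
            calls = rng.binomial(2, 0.5, (2, m)).astype(np.int8)
            calls[rng.random(calls.shape) < 0.02] = MISSING
            # plant a long homozygous stretch in sample 0
            lo = rng.integers(0, m - 120)
            calls[0, lo:lo + 120] = np.where(rng.random(120) < 0.5, 0, 2)
            segs, tot = detect_roh(_dataset(calls, pos), params)
            for i in range(2):
                want = _roh_brute_force(calls[i], pos, params)
                assert tot.iloc[i] == pytest.approx(want)

    def test_short_chromosome_skipped(self):
        pos = np.arange(1, 31) * 1000
        calls = np.zeros((1, 30), dtype=np.int8)
        segs, tot = detect_roh(_dataset(calls, pos))
        assert len(segs) == 0

    def test_first_cousin_offspring_autozygosity_near_one_sixteenth(self):
        # offspring of first cousins: inbreeding F = 1/16 of the genome
        # autozygous; detected ROH fraction sits just below (short segments
        # under the 1 Mb floor are missed)
        rng = np.random.default_rng(4)
        m = 1500
        genome_mb = 150.0
        pos = np.sort(rng.choice(int(genome_mb * 1e6), m, replace=False))
        cm = pos / 1e6  # 1 cM/Mb
        chrom = np.zeros(m, dtype=int)
        freqs = rng.uniform(0.3, 0.7, m)
        fracs = []
        for rep in range(40):
            gf, gm = (sample_haplotypes(freqs, 2, rng) for _ in range(2))
            p1 = drop_gametes(gf, gm, chrom, cm, rng)
            p2 = drop_gametes(gf, gm, chrom, cm, rng)
            a = drop_gametes(p1, sample_haplotypes(freqs, 2, rng), chrom, cm, rng)
            b = drop_gametes(p2, sample_haplotypes(freqs, 2, rng), chrom, cm, rng)
            child = drop_gametes(a, b, chrom, cm, rng)
            calls = child.sum(axis=0).astype(np.int8)[None, :]
            _, tot = detect_roh(_dataset(calls, pos))
            fracs.append(tot.iloc[0] / (genome_mb * 1000))
        assert np.mean(fracs) == pytest.approx(1 / 16, abs=0.02)


class TestInferSex:
    def _metrics(self, f, ratio):
        return pd.DataFrame({"id": [f"s{i}" for i in range(len(f))],
                             "chrx_f": f, "y_x_ratio": ratio})

    def _cohort(self, rng, n=60):
        f = np.concatenate([rng.normal(0.98, 0.02, n // 2),
                            rng.normal(0.02, 0.02, n // 2)])
        ratio = np.concatenate([rng.normal(2.0, 0.1, n // 2),
                                rng.normal(0.4, 0.05, n // 2)])
        sex = ["M"] * (n // 2) + ["F"] * (n // 2)
        return self._metrics(f, ratio), sex

    def test_concordant_samples_pass(self):
        rng = np.random.default_rng(5)
        met, sex = self._cohort(rng)
        calls = infer_sex(met, sex)
        assert all(c.call in ("XY", "XX") for c in calls)

    def test_mismatch_detected(self):
        rng = np.random.default_rng(6)
        met, sex = self._cohort(rng)
        sex[0] = "F"  # reported female, genetically male
        calls = infer_sex(met, sex)
        assert calls[0].call == "sex_mismatch"

    def test_xxy_like_intermediate_profile(self):
        rng = np.random.default_rng(7)
        met, sex = self._cohort(rng)
        met.loc[0, "chrx_f"] = 0.5
        met.loc[0, "y_x_ratio"] = 1.2
        calls = infer_sex(met, sex)  # reported male with chrX heterozygosity
        assert calls[0].call == "XXY_like"

    def test_missing_metric_unresolved(self):
        rng = np.random.default_rng(8)
        met, sex = self._cohort(rng)
        met.loc[0, "chrx_f"] = np.nan
        assert infer_sex(met, sex)[0].call == "unresolved"


class TestXAneuploidy:
    def _metrics(self, lrr):
        n = len(lrr)
        return pd.DataFrame({"id": [f"s{i}" for i in range(n)],
                             "chrx_lrr_mean": lrr})

    def _baf(self, sid, bands, n=80, noise=0.03, seed=0):
        rng = np.random.default_rng(seed)
        if not bands:
            return {sid: np.array([])}
        pick = rng.integers(len(bands), size=n)
        return {sid: np.clip(np.array(bands)[pick] + rng.normal(0, noise, n),
                             0, 1)}

    def test_normal_lrr_makes_no_call(self):
        rng = np.random.default_rng(9)
        lrr = rng.normal(0, 0.05, 50)
        met = self._metrics(lrr)
        baf = {f"s{i}": np.full(80, 0.5) for i in range(50)}
        assert classify_x_aneuploidy(met, baf, ["F"] * 50) == []

    def test_planted_xo_and_xxx_recovered(self):
        rng = np.random.default_rng(10)
        lrr = list(rng.normal(0, 0.05, 48)) + [-0.6, 0.4]
        met = self._metrics(lrr)
        baf = {f"s{i}": rng.normal(0.5, 0.03, 80) for i in range(48)}
        baf.update(self._baf("s48", ()))                 # XO: no het band
        baf.update(self._baf("s49", (1 / 3, 2 / 3)))     # XXX: 1/3, 2/3 bands
        calls = {c.sample: c.call
                 for c in classify_x_aneuploidy(met, baf, ["F"] * 50)}
        assert calls["s48"] == "XO"
        assert calls["s49"] == "XXX"

    def test_mosaic_xo_displaced_band(self):
        rng = np.random.default_rng(11)
        lrr = list(rng.normal(0, 0.05, 49)) + [-0.3 - 0.25]  # clearly low
        met = self._metrics(lrr)
        baf = {f"s{i}": rng.normal(0.5, 0.03, 80) for i in range(49)}
        baf.update(self._baf("s49", (0.33, 0.67), seed=3))
        calls = {c.sample: c.call
                 for c in classify_x_aneuploidy(met, baf, ["F"] * 50)}
        assert calls["s49"] == "XO_mosaic"

    def test_too_few_probes_unresolved(self):
        rng = np.random.default_rng(12)
        lrr = list(rng.normal(0, 0.05, 49)) + [0.5]
        met = self._metrics(lrr)
        baf = {f"s{i}": rng.normal(0.5, 0.03, 80) for i in range(49)}
        baf["s49"] = np.array([0.33, 0.67, 0.4])  # 3 probes only
        calls = {c.sample: c.call
                 for c in classify_x_aneuploidy(met, baf, ["F"] * 50)}
        assert calls["s49"] == "unresolved"

    def test_cohort_karyotype_recovery(self, small_cohort):
        ds, metrics, _, truth = small_cohort
        reported = ds.samples["sex"]
        calls = {c.sample: c.call for c in
                 classify_x_aneuploidy(metrics.table, metrics.baf, reported)}
        planted = {s: k for s, k in truth.karyotypes.items()
                   if k in ("XO", "XO_mosaic", "XXX")}
        hits = sum(calls.get(s) == k for s, k in planted.items())
        assert hits / len(planted) >= 0.8
        # no euploid female is called aneuploid
        euploid = [s for s, k in truth.karyotypes.items() if k == "XX"]
        assert all(calls.get(s) is None or calls[s] == "unresolved"
                   for s in euploid)


class TestPlateRotation:
    def _layout(self, n_rows=8, n_cols=12, plate="p1"):
        rows = []
        for r in range(n_rows):
            for c in range(n_cols):
                rows.append((plate, f"{chr(65 + r)}{c + 1:02d}"))
        df = pd.DataFrame(rows, columns=["plate", "well"])
        rng = np.random.default_rng(13)
        df["reported_sex"] = rng.choice(["M", "F"], size=len(df))
        df["inferred_sex"] = df["reported_sex"]
        return df

    def test_clean_plate_ok(self):
        assert detect_plate_orientation_errors(self._layout()) == {"p1": "ok"}

    def test_rotated_plate_detected(self):
        lay = self._layout()
        # physically rotate the plate: inferred sexes come from the 180-mapped well
        pos = {(w[0], int(w[1:])): s
               for w, s in zip(lay["well"], lay["reported_sex"])}
        rot = [pos[(chr(65 + (7 - (ord(w[0]) - 65))), 13 - int(w[1:]))]
               for w in lay["well"]]
        lay["inferred_sex"] = rot
        n_discord = (lay["inferred_sex"] != lay["reported_sex"]).sum()
        assert n_discord >= 8  # sex-informative discordances exist
        assert detect_plate_orientation_errors(lay) == {"p1": "rotated_180"}

    def test_random_mismatches_unresolved(self):
        lay = self._layout()
        flip = {"M": "F", "F": "M"}
        for i in (3, 40, 77):
            lay.loc[i, "inferred_sex"] = flip[lay.loc[i, "reported_sex"]]
        assert detect_plate_orientation_errors(lay) == {"p1": "unresolved"}

    def test_mass_simulation_no_false_rotations(self):
        # 300 clean plates and 300 rotated plates: perfect separation
        rng = np.random.default_rng(14)
        wrong = 0
        for rep in range(300):
            lay = self._layout(plate=f"p{rep}")
            lay["reported_sex"] = rng.choice(["M", "F"], size=len(lay))
            if rep % 2:
                pos = {(w[0], int(w[1:])): s
                       for w, s in zip(lay["well"], lay["reported_sex"])}
                lay["inferred_sex"] = [
                    pos[(chr(65 + (7 - (ord(w[0]) - 65))), 13 - int(w[1:]))]
                    for w in lay["well"]]
                informative = (lay["inferred_sex"] != lay["reported_sex"]).sum()
                want = "rotated_180" if informative >= 4 else "ok"
            else:
                lay["inferred_sex"] = lay["reported_sex"]
                want = "ok"
            got = detect_plate_orientation_errors(lay)[f"p{rep}"]
            if want == "rotated_180" and got != "rotated_180":
                wrong += 1
            if want == "ok" and got != "ok":
                wrong += 1
        assert wrong == 0


class TestAncestryOutliers:
    def test_boundary_not_flagged_at_9_9_sd(self):
        rng = np.random.default_rng(15)
        s = rng.normal(0, 1, (500, 10))
        s = (s - s.mean(0)) / s.std(0, ddof=1)
        s[0, 0] = 9.9 * 1.0  # just under the cutoff on standardised scale
        out = ancestry_outliers(s * 1.0)
        assert not out["fail_ancestry"][0]

    def test_distant_sample_flagged(self):
        rng = np.random.default_rng(16)
        s = rng.normal(0, 1, (500, 10))
        s[0, 3] = 30.0
        out = ancestry_outliers(s)
        assert out["fail_ancestry"][0]
        assert out["fail_ancestry"].sum() == 1


class TestFindDuplicates:
    def test_planted_duplicates_found_and_resolved(self, small_cohort):
        ds, _, _, truth = small_cohort
        expected = [(i, j) for i, j, k in truth.relationships
                    if k in ("intentional_duplicate", "repeat_participant")]
        out = find_duplicates(ds, n_thin=400, expected_pairs=expected)
        found = {frozenset((r.i, r.j)) for r in out.itertuples()
                 if r.status != "missing_expected"}
        for pair in expected:
            assert frozenset(pair) in found
        assert (out.loc[out["status"] != "missing_expected", "pi_hat"]
                > 0.95).all()

    def test_duplicate_with_genotype_errors_still_detected(self):
        rng = np.random.default_rng(17)
        m = 4000
        freqs = rng.uniform(0.1, 0.9, m)
        base = rng.binomial(2, freqs, (6, m)).astype(np.int8)
        base[1] = base[0]
        err = rng.random(m) < 0.01
        base[1, err] = rng.binomial(2, freqs[err])
        ds = _dataset(base, np.arange(1, m + 1) * 100)
        out = find_duplicates(ds, n_thin=m)
        pairs = {frozenset((r.i, r.j)): r.pi_hat for r in out.itertuples()}
        assert frozenset(("s0", "s1")) in pairs
        assert pairs[frozenset(("s0", "s1"))] > 0.97
        assert len(pairs) == 1  # unrelated samples are not reported

    def test_missing_expected_duplicate_raises_alert(self):
        rng = np.random.default_rng(18)
        m = 2000
        calls = rng.binomial(2, 0.5, (4, m)).astype(np.int8)
        ds = _dataset(calls, np.arange(1, m + 1) * 100)
        out = find_duplicates(ds, n_thin=m, expected_pairs=[("s0", "s1")])
        assert (out["status"] == "missing_expected").any()


class TestCompileReport:
    def test_all_pass_when_no_flags(self):
        rep = compile_sample_report(["a", "b"], {})
        assert (rep["status"] == "pass").all()

    def test_multiple_flags_single_primary_status(self):
        rep = compile_sample_report(
            ["a"], {"fail_het_high": ["a"], "fail_sex_mismatch": ["a"]})
        assert rep["status"][0] == "fail_het_high"
        assert rep["evidence_flags"][0] == "fail_het_high;fail_sex_mismatch"

    def test_totals_reconcile(self):
        ids = [f"s{i}" for i in range(20)]
        flags = {"fail_callrate": ids[:3], "fail_ancestry": ids[2:5]}
        rep = compile_sample_report(ids, flags)
        assert (rep["status"] == "pass").sum() + \
            (rep["status"] != "pass").sum() == 20
        assert (rep["status"] != "pass").sum() == 5

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="unknown status"):
            compile_sample_report(["a"], {"fail_bogus": ["a"]})
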