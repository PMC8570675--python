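import numpy as np
import pandas as pd
import pytest

from mirpipe.annotate import annotate_table
from mirpipe.biomarker import univariate_fits
from mirpipe.hairpin import evaluate_criteria, extract_features, fold
from mirpipe.preprocess import CleanParams, clean_reads, collapse_unique
from mirpipe.quantify import build_count_matrix
from mirpipe.seqio import write_fasta, write_fastq
from mirpipe.simulate import (
    CohortSimConfig,
    ReadSimConfig,
    generate_reference,
    simulate_cohort,
    simulate_sample_reads,
)


class TestGenerateReference:
    def test_rejects_zero_precursors(self):
        with pytest.raises(ValueError):
            generate_reference(0, 0, seed=1)

    def test_seeded_determinism_byte_identical(self, tmp_path):
        paths = []
        for i in (1, 2):
            ref = generate_reference(5, 3, seed=1)
            p = tmp_path / f"ref{i}.fa"
            write_fasta(ref.to_reference("both").to_fasta_records(), p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_mature_lengths_in_range(self):
        ref = generate_reference(3, 2, seed=2)
        # brute-force scan of every record
        for rec in ref.precursors:
            assert len(rec.sequence) >= 50
            for m in rec.matures:
                assert 20 <= m.end - m.start <= 24
                assert 0 <= m.start < m.end <= len(rec.sequence)

    def test_construction_guarantees_stem(self):
        ref = generate_reference(1, 0, seed=7)
        rec = ref.precursors[0]
        st = fold(rec.sequence)
        m = rec.matures[0]
        feats = extract_features(st, (m.start, m.end))
        assert feats.stem_bp >= 16

    def test_criteria_2_4_5_pass_by_construction(self):
        ref = generate_reference(12, 0, seed=3)
        for rec in ref.precursors:
            st = fold(rec.sequence)
            m = rec.matures[0]
            feats = extract_features(st, (m.start, m.end))
            report = evaluate_criteria(feats, st.energy)
            assert report.c2 and report.c4 and report.c5, rec.id

    def test_contaminant_families_cycle(self):
        ref = generate_reference(1, 5, seed=4)
        families = [c.description.split("=")[1] for c in ref.contaminants]
        assert families[:4] == ["rRNA", "tRNA", "snRNA", "snoRNA"]


class TestSimulateSampleReads:
    def test_degenerate_noise_reads_exact(self, small_reference):
        ref = small_reference
        mid = ref.precursors[0].matures[0].name
        cfg = ReadSimConfig(n_reads=100, fraction_junk=0.0,
                            fraction_contaminant=0.0, end_variation_max=0,
                            mismatch_rate=0.0, dispersion=0.0, seed=5)
        reads = simulate_sample_reads(ref, {mid: 100}, cfg)
        mature = ref.mature_sequences()[mid]
        assert len(reads) > 0
        for r in reads:
            assert r.sequence == mature + cfg.adapter
            assert set(r.qualities) == {40}

    def test_seeded_determinism_fastq_bytes(self, small_reference, tmp_path):
        mid = small_reference.precursors[0].matures[0].name
        cfg = ReadSimConfig(n_reads=200, seed=6)
        blobs = []
        for i in (1, 2):
            reads = simulate_sample_reads(small_reference, {mid: 50}, cfg)
            p = tmp_path / f"r{i}.fastq"
            write_fastq(reads, p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]

    def test_empty_expression_only_junk_contaminant(self, small_reference):
        cfg = ReadSimConfig(n_reads=200, fraction_junk=0.1,
                            fraction_contaminant=0.1, seed=7)
        reads = simulate_sample_reads(small_reference, {}, cfg)
        assert len(reads) == 40
        contams = [c.sequence for c in small_reference.contaminants]
        for r in reads:
            insert = r.sequence[:-len(cfg.adapter)]
            is_contam = any(insert in c for c in contams)
            is_junk = len(set(insert)) <= 2
            assert is_contam or is_junk

    def test_unknown_expression_key_rejected(self, small_reference):
        with pytest.raises(ValueError, match="not in reference"):
            simulate_sample_reads(small_reference, {"nope": 10},
                                  ReadSimConfig(seed=1))

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            ReadSimConfig(fraction_junk=0.6, fraction_contaminant=0.6)
        with pytest.raises(ValueError):
            ReadSimConfig(end_variation_max=3)

    def test_closure_after_adapter_removal(self, small_reference):
        # every non-junk, non-contaminant insert lies within one mismatch
        # of some precursor subsequence
        mids = [p.matures[0].name for p in small_reference.precursors]
        cfg = ReadSimConfig(n_reads=300, fraction_junk=0.1,
                            fraction_contaminant=0.1, end_variation_max=2,
                            mismatch_rate=0.3, seed=8)
        reads = simulate_sample_reads(small_reference,
                                      {m: 30 for m in mids}, cfg)
        contams = [c.sequence for c in small_reference.contaminants]
        pres = [p.sequence for p in small_reference.precursors]
        for r in reads:
            insert = r.sequence[:-len(cfg.adapter)]
            if any(insert in c for c in contams) or len(set(insert)) <= 2:
                continue
            ok = False
            for pre in pres:
                for off in range(len(pre) - len(insert) + 1):
                    mm = sum(a != b for a, b in
                             zip(insert, pre[off:off + len(insert)]))
                    if mm <= 1:
                        ok = True
                        break
                if ok:
                    break
            assert ok, insert

    def test_parameter_recovery_through_pipeline(self, small_reference):
        # mean recovered counts across replicate samples within 3 SE
        ref = small_reference
        m1 = ref.precursors[0].matures[0].name
        m2 = ref.precursors[1].matures[0].name
        reference = ref.to_reference("both")
        recovered = {m1: [], m2: []}
        adapter = ReadSimConfig().adapter
        params = CleanParams(adapter=adapter)
        for rep in range(10):
            cfg = ReadSimConfig(n_reads=300, fraction_junk=0.0,
                                fraction_contaminant=0.0, seed=100 + rep)
            reads = simulate_sample_reads(ref, {m1: 50, m2: 200}, cfg)
            accepted, stats = clean_reads(reads, params)
            table = collapse_unique({"s": accepted}, {"s": stats})
            matrix = build_count_matrix(annotate_table(table, reference))
            for mid in (m1, m2):
                recovered[mid].append(
                    float(matrix.counts.loc[mid, "s"])
                    if mid in matrix.counts.index else 0.0)
        for mid, target in ((m1, 50.0), (m2, 200.0)):
            vals = np.array(recovered[mid])
            se = vals.std(ddof=1) / np.sqrt(len(vals)) or 1.0
            assert abs(vals.mean() - target) <= 3 * max(se, 1.0)


class TestSimulateCohort:
    def _levels(self, n, value=1000.0):
        return {f"s{i:02d}": {"mir-x": value} for i in range(n)}

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            CohortSimConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            CohortSimConfig(n_per_group={"a": 1, "b": 5})

    def test_zero_slope_tiny_noise_scores_at_intercept(self):
        cfg = CohortSimConfig(n_per_group={"a": 5, "b": 5},
                              pain_prevalence={}, interference_slope=0.0,
                              noise_sd=1e-9, seed=1)
        cohort = simulate_cohort(cfg, self._levels(10))
        assert np.allclose(cohort["interference_mood"],
                           cfg.interference_intercept)

    def test_forced_pain_assignment(self):
        cfg = CohortSimConfig(
            n_per_group={"a": 10, "b": 10},
            pain_prevalence={"a": 1.0, "b": 0.0}, seed=2)
        cohort = simulate_cohort(cfg, self._levels(20))
        assert (cohort.loc[cohort["group"] == "a",
                           "neuropathic_pain"] == 1).all()
        assert (cohort.loc[cohort["group"] == "b",
                           "neuropathic_pain"] == 0).all()

    def test_seeded_determinism(self):
        cfg = CohortSimConfig(n_per_group={"a": 5, "b": 5}, seed=3)
        c1 = simulate_cohort(cfg, self._levels(10))
        c2 = simulate_cohort(cfg, self._levels(10))
        pd.testing.assert_frame_equal(c1, c2)

    def test_scores_clipped(self):
        cfg = CohortSimConfig(n_per_group={"a": 30, "b": 30},
                              interference_slope=1.0, noise_sd=5.0, seed=4)
        cohort = simulate_cohort(cfg, self._levels(60, value=100.0))
        assert cohort["interference_mood"].between(0, 10).all()

    def test_slope_recovery_univariate(self):
        # planted slope recovered within 3 SE by the downstream fit
        rng = np.random.default_rng(5)
        levels = {f"s{i:02d}": {"mir-x": float(rng.uniform(0, 5000))}
                  for i in range(60)}
        cfg = CohortSimConfig(n_per_group={"a": 30, "b": 30},
                              interference_slope=0.0004, noise_sd=1.0,
                              interference_intercept=4.0, seed=6)
        cohort = simulate_cohort(cfg, levels)
        fit = univariate_fits(cohort["interference_mood"],
                              cohort[["mir-x"]])["mir-x"]
        assert abs(fit.coef["mir-x"] - 0.0004) <= 3 * fit.se["mir-x"]
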