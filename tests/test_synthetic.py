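"""Synthetic window generator and the planted toy annotation."""

import numpy as np
import pytest

from splicedisp import simulate as sim
from splicedisp.catalog import TranscriptModel
from splicedisp.dispersion import count_kmers_by_site
from splicedisp.windows import label_to_offset


class TestGenerateWindows:
    def test_deterministic_given_seed(self):
        cfg = sim.GeneratorConfig(n_per_mode=50, seed=9)
        a = [w.sequence for w in sim.generate_windows(cfg, "common")]
        b = [w.sequence for w in sim.generate_windows(cfg, "common")]
        assert a == b

    def test_modes_use_distinct_streams(self):
        cfg = sim.GeneratorConfig(n_per_mode=50, seed=9)
        a = [w.sequence for w in sim.generate_windows(cfg, "common")]
        b = [w.sequence for w in sim.generate_windows(cfg, "alternative")]
        assert a != b

    def test_canonical_ag_always_fixed(self):
        cfg = sim.GeneratorConfig(n_per_mode=200, seed=1)
        for w in sim.generate_windows(cfg, "alternative"):
            assert w.base_at(-2) == "A" and w.base_at(-1) == "G"
            assert w.canonical_ag

    def test_upstream_pyrimidine_fraction(self):
        """Empirical C+T fraction over the upstream tract matches the target
        within a 99% binomial interval."""
        target = 0.8
        cfg = sim.GeneratorConfig(
            n_per_mode=5000, seed=2, upstream_pyrimidine_fraction=target
        )
        windows = sim.generate_windows(cfg, "common")
        offsets = [label_to_offset(lab) for lab in range(-50, -7)]
        n_bases = len(windows) * len(offsets)
        count = sum(
            1 for w in windows for o in offsets if w.sequence[o] in "CT"
        )
        half_width = 2.576 * np.sqrt(target * (1 - target) / n_bases)
        assert abs(count / n_bases - target) < half_width

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sim.GeneratorConfig(n_per_mode=0)
        with pytest.raises(ValueError):
            sim.GeneratorConfig(upstream_pyrimidine_fraction=1.5)
        with pytest.raises(ValueError):
            sim.GeneratorConfig(downstream_composition=(0.5, 0.5, 0.5, 0.5))


class TestInjection:
    @staticmethod
    def _mean_pattern_count(windows, pattern, start_label, end_label):
        lo, hi = label_to_offset(start_label), label_to_offset(end_label)
        return np.mean(
            [
                sum(
                    w.sequence[o : o + 2] == pattern
                    for o in range(lo, hi)
                )
                for w in windows
            ]
        )

    def test_injection_enriches_target_mode_only(self):
        inj = sim.Injection("AG", 5, 30, 3.0, "alternative")
        cfg = sim.GeneratorConfig(n_per_mode=1000, seed=3, injections=(inj,))
        enriched = sim.generate_windows(cfg, "alternative")
        null = sim.generate_windows(cfg, "common")
        m_enriched = self._mean_pattern_count(enriched, "AG", 5, 30)
        m_null = self._mean_pattern_count(null, "AG", 5, 30)
        assert m_enriched > 2.0 * m_null

    def test_infeasible_injection_rejected(self):
        inj = sim.Injection("AG", 5, 30, 500.0, "alternative")
        cfg = sim.GeneratorConfig(n_per_mode=10, seed=3, injections=(inj,))
        with pytest.raises(ValueError):
            sim.generate_windows(cfg, "alternative")

    def test_invalid_injection_pattern(self):
        with pytest.raises(ValueError):
            sim.Injection("AGT", 5, 30, 3.0, "alternative")
        with pytest.raises(ValueError):
            sim.Injection("AG", 5, 30, -1.0, "alternative")


class TestNullPair:
    def test_sizes_and_independence(self):
        cfg = sim.GeneratorConfig(n_per_mode=100, seed=4)
        a, b = sim.generate_null_pair(cfg)
        assert len(a) == len(b) == 100
        assert [w.sequence for w in a] != [w.sequence for w in b]

    def test_profiles_agree_within_noise(self, partition6):
        """Null-pair dispersion curves stay inside a Monte-Carlo noise envelope.

        The envelope is the largest per-site |delta rho| (XY1, all patterns)
        seen across reference null replicates of the same generator; a
        further independent pair must not exceed it by more than a safety
        factor.
        """
        from splicedisp.dispersion import profile
        from splicedisp.region_stats import _region_matrix, RegionSpec

        whole = RegionSpec("whole", -50, 45)

        def max_delta_rho(seed):
            cfg = sim.GeneratorConfig(n_per_mode=500, seed=seed)
            a, b = sim.generate_null_pair(cfg)
            pa = profile(count_kmers_by_site(a), partition6)
            pb = profile(count_kmers_by_site(b), partition6)
            ma = _region_matrix(pa, whole, "XY1")
            mb = _region_matrix(pb, whole, "XY1")
            return float((ma - mb).abs().to_numpy().max())

        envelope = max(max_delta_rho(1000 + r) for r in range(10))
        assert max_delta_rho(5) <= 1.5 * envelope


class TestToyAnnotation:
    def test_deterministic(self):
        a = sim.generate_toy_annotation(0)
        b = sim.generate_toy_annotation(0)
        assert a.genome == b.genome and a.gtf == b.gtf

    def test_truth_table_contents(self):
        toy = sim.generate_toy_annotation(0)
        truth = toy.truth
        assert set(truth["mode"]) == {"common", "constitutive", "alternative", "ambiguous"}
        alt = truth[truth["mode"] == "alternative"]
        assert set(alt["submode"]) == {"normal", "exonic", "intronic"}
        assert (truth["filter_reason"] == "short_intron").sum() == 1
        assert (truth["filter_reason"] == "alt_proximity").sum() == 2

    def test_every_intron_is_canonical(self, toy):
        genome = toy["annotation"].genome
        for model in toy["models"].values():
            for s, e in model.introns():
                seq = genome[model.chrom][s - 1 : e]
                if model.strand == "+":
                    assert seq[:2] == "GT" and seq[-2:] == "AG"
                else:
                    assert seq[:2] == "CT" and seq[-2:] == "AC"

    def test_written_files_parse(self, toy):
        assert toy["paths"]["genome"].exists()
        assert len(toy["models"]) == 19
        assert len(toy["events"]) == 19


def test_transcript_model_introns():
    m = TranscriptModel("t", "c", "+", [(101, 200), (301, 400), (501, 600)])
    assert m.introns() == [(201, 300), (401, 500)]
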