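"""Generator contracts: determinism, planted effects, recoverability."""

import numpy as np
import pandas as pd
import pytest

from torpormir import (
    ArrayConfig,
    AssayConfig,
    QpcrConfig,
    ddct_ratio,
    filter_noninformative,
    generate_array,
    generate_assay_tables,
    generate_qpcr,
)
from torpormir.synthetic import (
    random_mature_mirna,
    synthetic_family_table,
    target_with_planted_sites,
)


class TestGenerateArray:
    def test_same_seed_bit_identical(self):
        cfg = ArrayConfig(n_probes=200, seed=11)
        m1, t1 = generate_array(cfg)
        m2, t2 = generate_array(cfg)
        assert m1.values.equals(m2.values)
        assert t1.probe_truth.equals(t2.probe_truth)

    def test_different_seed_differs(self):
        m1, _ = generate_array(ArrayConfig(n_probes=200, seed=1))
        m2, _ = generate_array(ArrayConfig(n_probes=200, seed=2))
        assert not m1.values.equals(m2.values)

    def test_planted_family_effect_by_construction(self):
        cfg = ArrayConfig(
            n_probes=2000, noise_floor=50.0, seed=1,
            planted_families=(("miR-200", -3.0),),
        )
        _, truth = generate_array(cfg)
        planted = truth.probe_truth[truth.probe_truth["family"] == "miR-200"]
        assert len(planted) > 0
        assert planted["is_differential"].all()
        np.testing.assert_allclose(
            planted["true_mean_LH"], planted["true_mean_ACR"] / 3.0
        )

    def test_unplanted_probes_are_null(self):
        _, truth = generate_array(ArrayConfig(n_probes=300, seed=3))
        assert (truth.probe_truth["true_mean_ACR"]
                == truth.probe_truth["true_mean_LH"]).all()

    def test_probe_ids_unique_and_mirbase_style(self):
        m, _ = generate_array(ArrayConfig(n_probes=500, seed=5))
        assert not m.probe_ids.has_duplicates
        assert all("-" in pid and ("miR" in pid or "let" in pid)
                   for pid in m.probe_ids)

    def test_truth_invariants(self):
        cfg = ArrayConfig(n_probes=300, seed=9,
                          planted_families=(("miR-96", 2.5),))
        _, truth = generate_array(cfg)
        assert truth.noise_floor > 0
        assert truth.design["n_ACR"] >= 2 and truth.design["n_LH"] >= 2
        pt = truth.probe_truth
        assert pt["family"].notna().all() and pt["species"].notna().all()
        diff = pt[pt["is_differential"]]
        assert (diff["planted_fold"].abs() >= 1).all()

    @pytest.mark.parametrize(
        "kwargs, msg",
        [
            (dict(noise_floor=-1.0), "noise_floor"),
            (dict(planted_families=(("miR-1", 0.5),)), "magnitude"),
            (dict(n_families=1, planted_families=(("miR-1", 2.0), ("miR-2", 2.0))),
             "planted"),
            (dict(n_probes=10), "n_probes"),
            (dict(n_per_group=1), "n_per_group"),
        ],
    )
    def test_invalid_config_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            generate_array(ArrayConfig(**kwargs))

    def test_all_background_array_is_filterable(self):
        """With nothing expressed, filtering at the true floor removes ~all
        probes (Monte-Carlo over 20 seeds, mean retained fraction < 5%)."""
        retained = []
        for seed in range(20):
            cfg = ArrayConfig(n_probes=1000, noise_floor=50.0,
                              fraction_expressed=0.0, seed=seed)
            m, truth = generate_array(cfg)
            kept, _ = filter_noninformative(m, truth.noise_floor)
            retained.append(kept.n_probes / m.n_probes)
        assert np.mean(retained) < 0.05


class TestGenerateQpcr:
    def test_noiseless_sixteen_fold_gives_ddct_4(self):
        cfg = QpcrConfig(mirnas=("miR-103", "miR-182"),
                         true_ratios={"miR-182": 1 / 16}, ct_noise_sd=0.0)
        ct = generate_qpcr(cfg)
        res = ddct_ratio(ct, "miR-182", "LH", "ACR")
        assert res["ddct"] == pytest.approx(4.0, abs=1e-12)
        assert res["ratio"] == pytest.approx(1 / 16, rel=1e-12)

    def test_noiseless_null_ratio_gives_ddct_0(self):
        cfg = QpcrConfig(mirnas=("miR-103", "miR-9"),
                         true_ratios={"miR-9": 1.0}, ct_noise_sd=0.0)
        res = ddct_ratio(generate_qpcr(cfg), "miR-9", "LH", "ACR")
        assert res["ddct"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_ratio_recovered_in_expectation(self):
        """ct_noise_sd=0.2: mean recovered ratio within 10% of 1/16 over
        many seeds (Monte-Carlo)."""
        ratios = []
        for seed in range(100):
            cfg = QpcrConfig(mirnas=("miR-103", "miR-182"),
                             true_ratios={"miR-182": 1 / 16},
                             ct_noise_sd=0.2, seed=seed)
            ratios.append(ddct_ratio(generate_qpcr(cfg), "miR-182",
                                     "LH", "ACR")["ratio"])
        assert np.mean(ratios) == pytest.approx(1 / 16, rel=0.10)

    def test_reference_flat_across_groups_when_noiseless(self):
        cfg = QpcrConfig(mirnas=("miR-103", "miR-1"), ct_noise_sd=0.0)
        ct = generate_qpcr(cfg)
        ref = ct[ct["mirna"] == "miR-103"]
        assert ref["ct"].nunique() == 1

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            generate_qpcr(QpcrConfig(mirnas=("miR-182",)))

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_qpcr(QpcrConfig(mirnas=("miR-103", "miR-1"),
                                     true_ratios={"miR-1": -2.0}))


class TestGenerateAssayTables:
    def test_noiseless_tables_encode_planted_values(self):
        cfg = AssayConfig(noise_cv=0.0)
        dens, absorb, lum = generate_assay_tables(cfg)
        lh = dens[dens["group"] == "LH"]
        np.testing.assert_allclose(
            lh["target_band"] / lh["actin_band"],
            2.0 * cfg.band_base_ratio,
        )
        ogd = absorb[absorb["condition"] == "OGD"]
        np.testing.assert_allclose(
            ogd["a450"] - ogd["a690"], 0.35 * cfg.control_corrected
        )
        rep = lum[lum["construct"] == "UBE2I_miR-182"]
        np.testing.assert_allclose(
            rep["firefly"] / rep["renilla"], 0.6 * cfg.control_ratio
        )

    def test_out_of_range_absorbance_rejected(self):
        with pytest.raises(ValueError, match="absorbance"):
            generate_assay_tables(
                AssayConfig(viability_fractions={"control": 1.0, "x": 10.0})
            )

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_assay_tables(
                AssayConfig(densitometry_ratios={"ACR": 1.0, "LH": -1.0})
            )

    def test_determinism(self):
        a = generate_assay_tables(AssayConfig(noise_cv=0.1, seed=3))
        b = generate_assay_tables(AssayConfig(noise_cv=0.1, seed=3))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestSequenceFixtures:
    def test_mirna_alphabet_and_length(self):
        s = random_mature_mirna(22, seed=1)
        assert len(s) == 22 and set(s) <= set("ACGU")

    def test_planted_site_is_seed_complement(self):
        mir = random_mature_mirna(22, seed=2)
        t = target_with_planted_sites(mir, [50], "8mer", length=120, seed=3)
        comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
        core = "".join(comp[b] for b in reversed(mir[1:7]))
        assert t[50:56] == core
        assert t[49] == comp[mir[7]]
        assert t[56] == "A"


class TestSyntheticFamilyTable:
    def test_shape_and_threshold(self):
        df = synthetic_family_table()
        assert len(df) == 405
        assert (df["fold"].abs() >= 1.25).all()
        assert not df["probe_id"].duplicated().any()
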