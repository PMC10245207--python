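"""Synthetic survey generator: determinism, design, ground-truth structure."""

import dataclasses

import numpy as np
import pytest

import noduletrade as nt
from noduletrade.synthetic import (
    CladeSpec,
    ConfigError,
    GenusSpec,
    uniform_compatibility,
)
from noduletrade.traits import coefficient_of_variation, sphere_volume


def small_config(**overrides):
    """Two genera, two clades, four nests; fast to simulate."""
    base = dict(
        genera=(
            GenusSpec("Big", 2.0, 0.1, 2),
            GenusSpec("Small", 1.0, 0.05, 2),
        ),
        clades=(CladeSpec("A", 1.5, 15.0), CladeSpec("B", 0.6, 15.0)),
        compatibility={"Big": {"A": 1.0}, "Small": {"B": 1.0}},
        production_limit_L=20.0,
        density_noise_sigma=0.3,
        nodules_per_nest=20,
        workers_per_nest=3,
        seed=11,
    )
    base.update(overrides)
    return nt.SurveyConfig(**base)


class TestDefaultConfig:
    def test_passes_invariants_and_survey_design(self):
        cfg = nt.default_config()
        cfg.validate()
        assert len(cfg.genera) == 4
        assert len(cfg.clades) == 7
        assert cfg.n_nests_total == 43
        assert cfg.nodules_per_nest == 50
        assert cfg.workers_per_nest == 3

    def test_genus_size_ranking(self):
        """Head widths order Macrotermes > Odontotermes > Ancistrotermes >
        Microtermes."""
        cfg = nt.default_config()
        ordered = sorted(
            cfg.genera, key=lambda g: g.head_width_mean, reverse=True
        )
        assert [g.name for g in ordered] == [
            "Macrotermes",
            "Odontotermes",
            "Ancistrotermes",
            "Microtermes",
        ]

    def test_clade_cvs_inside_observed_band(self):
        cfg = nt.default_config()
        for clade in cfg.clades:
            assert 12.4 <= clade.diameter_cv <= 31.9


class TestSimulateSurvey:
    def test_table_shapes_and_id_consistency(self, default_survey):
        nod, nst = default_survey.nodule_table, default_survey.nest_table
        assert len(nod) == 43 * 50
        assert len(nst) == 43
        assert set(nod["nest_id"]) == set(nst["nest_id"])

    def test_seed_determinism_bit_identical(self, tmp_path):
        cfg = small_config()
        a = nt.simulate_survey(cfg)
        b = nt.simulate_survey(small_config())
        pa = a.write_csvs(tmp_path / "a")
        pb = b.write_csvs(tmp_path / "b")
        for fa, fb in zip(pa, pb):
            assert fa.read_bytes() == fb.read_bytes()

    def test_noise_free_isoquant_exact(self):
        cfg = small_config(density_noise_sigma=0.0)
        survey = nt.simulate_survey(cfg)
        product = survey.true_volumes() * survey.nest_table["density_per_g"]
        assert np.max(np.abs(product - cfg.production_limit_L)) < 1e-9

    def test_appending_nests_keeps_earlier_draws(self):
        """Hierarchical per-nest streams: growing the survey must not
        perturb already-generated nests."""
        cfg = small_config()
        bigger = small_config(
            genera=(
                cfg.genera[0],
                dataclasses.replace(cfg.genera[1], n_nests=3),
            )
        )
        a = nt.simulate_survey(cfg)
        b = nt.simulate_survey(bigger)
        n = len(a.nodule_table)
        assert b.nodule_table.iloc[:n].equals(a.nodule_table)
        assert (
            b.nest_table.iloc[: len(a.nest_table)].equals(a.nest_table)
        )

    def test_compatibility_respected(self, default_survey):
        compat = default_survey.truth.compatibility
        for genus, grp in default_survey.nest_table.groupby("genus"):
            allowed = {c for c, w in compat[genus].items() if w > 0}
            assert set(grp["clade"]) <= allowed

    def test_zero_weight_clade_never_drawn(self):
        cfg = small_config(
            compatibility={"Big": {"A": 1.0, "B": 0.0}, "Small": {"B": 1.0}}
        )
        survey = nt.simulate_survey(cfg)
        big = survey.nest_table[survey.nest_table["genus"] == "Big"]
        assert set(big["clade"]) == {"A"}

    def test_pooled_diameter_cv_converges_to_configured(self):
        """Empirical clade CV approaches the generating CV at large n."""
        cfg = small_config(nodules_per_nest=5000, seed=3)
        survey = nt.simulate_survey(cfg)
        for clade in cfg.clades:
            diam = survey.nodule_table.loc[
                survey.nodule_table["clade"] == clade.name, "diameter_mm"
            ]
            cv = coefficient_of_variation(diam)
            assert cv == pytest.approx(clade.diameter_cv, rel=0.02)

    def test_default_survey_pooled_cvs_inside_configured_band(
        self, default_survey
    ):
        cfg = default_survey.truth
        lo = min(c.diameter_cv for c in cfg.clades)
        hi = max(c.diameter_cv for c in cfg.clades)
        for clade in cfg.clades:
            diam = default_survey.nodule_table.loc[
                default_survey.nodule_table["clade"] == clade.name,
                "diameter_mm",
            ]
            cv = coefficient_of_variation(diam)
            assert lo * 0.8 <= cv <= hi * 1.2

    def test_round_density_gives_integer_counts(self):
        survey = nt.simulate_survey(small_config(round_density=True))
        dens = survey.nest_table["density_per_g"]
        assert np.array_equal(dens, np.round(dens))

    def test_mean_density_matches_isoquant_truth(self):
        """Median density per clade tracks L / V_true (lognormal median
        = 1 at any sigma)."""
        cfg = small_config(density_noise_sigma=0.4, seed=5)
        many = dataclasses.replace(
            cfg,
            genera=(
                dataclasses.replace(cfg.genera[0], n_nests=200),
                cfg.genera[1],
            ),
        )
        survey = nt.simulate_survey(many)
        a_nests = survey.nest_table[survey.nest_table["clade"] == "A"]
        expected = cfg.production_limit_L / sphere_volume(1.5)
        assert np.median(a_nests["density_per_g"]) == pytest.approx(
            expected, rel=0.1
        )


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(genera=()),
            dict(clades=()),
            dict(production_limit_L=0.0),
            dict(density_noise_sigma=-0.1),
            dict(nodules_per_nest=0),
            dict(compatibility={"Big": {}, "Small": {"B": 1.0}}),
            dict(compatibility={"Big": {"A": 0.0}, "Small": {"B": 1.0}}),
            dict(compatibility={"Big": {"A": -1.0}, "Small": {"B": 1.0}}),
            dict(compatibility={"Big": {"Z": 1.0}, "Small": {"B": 1.0}}),
        ],
        ids=[
            "no-genera",
            "no-clades",
            "zero-limit",
            "negative-sigma",
            "zero-nodules",
            "no-compatible-clades",
            "all-zero-weights",
            "negative-weight",
            "unknown-clade",
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigError):
            nt.simulate_survey(small_config(**bad))

    def test_degenerate_truncation_rejected(self):
        # mean 0.1 mm, sd 0.05: >1% of mass below the 0.05 mm floor
        with pytest.raises(ConfigError, match="truncation"):
            small_config(
                clades=(CladeSpec("A", 0.1, 50.0), CladeSpec("B", 0.6, 15.0))
            ).validate()

    def test_head_width_sd_must_be_below_mean(self):
        with pytest.raises(ConfigError):
            GenusSpec("G", 1.0, 1.0, 2).validate()


class TestSerialization:
    def test_yaml_roundtrip_reproduces_survey(self, tmp_path):
        cfg = small_config()
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        cfg2 = nt.SurveyConfig.from_yaml(path)
        assert cfg2 == cfg
        a = nt.simulate_survey(cfg)
        b = nt.simulate_survey(cfg2)
        assert a.nodule_table.equals(b.nodule_table)
        assert a.nest_table.equals(b.nest_table)

    def test_uniform_compatibility_flattens_weights(self):
        flat = uniform_compatibility(nt.default_config())
        for genus in flat.genera:
            weights = flat.compatibility[genus.name]
            assert set(weights) == {c.name for c in flat.clades}
            assert all(w == 1.0 for w in weights.values())
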