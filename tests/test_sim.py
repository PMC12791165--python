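"""Synthetic-data generators: designs, traces, genotypes, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from npqmap.sim import (
    MeasurementSchedule,
    TruthSpec,
    build_design,
    default_truth,
    draw_causal_gene_latents,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_trace,
    simulate_trace_batch,
)
from npqmap.sim.annotation import simulate_annotation
from npqmap.sim.traces import npq_induction
from npqmap.traits import KINETIC_PARAMS
from tests.conftest import PANEL_PARAMS


class TestDesign:
    def test_counts_of_small_augmented_design(self):
        d = build_design(10, 2, 1, 4, 6, seed=1, years=("2017",))
        assert len(d) == 11  # 9 uniques + the check in both blocks
        assert d["accession"].nunique() == 10
        assert d[d["is_check"]].shape[0] == 2

    def test_checks_connect_every_block(self):
        d = build_design(40, 4, 2, 8, 8, seed=0)
        for year, dy in d.groupby("year"):
            checks = dy[dy["is_check"]]
            assert set(checks["block"]) == set(dy["block"])
            # non-check accessions appear exactly once per year
            counts = dy[~dy["is_check"]]["accession"].value_counts()
            assert (counts == 1).all()

    def test_unique_grid_position_per_year(self):
        d = build_design(40, 4, 2, 8, 8, seed=0)
        assert not d.duplicated(["row", "col", "year"]).any()

    def test_no_checks_rejected(self):
        with pytest.raises(ValueError, match="check"):
            build_design(10, 2, 0, 4, 6, seed=1)

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="plots"):
            build_design(30, 2, 1, 4, 6, seed=1)

    def test_same_seed_same_design(self):
        a = build_design(20, 2, 1, 6, 6, seed=5)
        b = build_design(20, 2, 1, 6, 6, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSchedule:
    def test_default_schedule_valid(self):
        s = MeasurementSchedule()
        assert s.light_times[-1] == 10 and s.dark_times[-1] == 12

    @pytest.mark.parametrize(
        "light,dark",
        [
            ((1, 2, 3, 9), (1, 2, 3, 12)),  # light must end at 10
            ((1, 2, 10, 10), (1, 2, 3, 12)),  # not strictly increasing
            ((1, 2, 3, 10), (1, 2, 3, 11)),  # dark must end at 12
        ],
    )
    def test_invalid_schedules_rejected(self, light, dark):
        with pytest.raises(ValueError):
            MeasurementSchedule(light_times=light, dark_times=dark)


class TestTraces:
    def test_npq_closed_form_at_one_minute(self):
        # a (1 - exp(-k t)) with a=2.8, k=0.58 evaluates to 1.2442 at t=1
        assert npq_induction(np.array([1.0]), 2.8, 0.58) == pytest.approx(
            2.8 * (1 - np.exp(-0.58)), abs=1e-12
        )
        assert npq_induction(np.array([1.0]), 2.8, 0.58)[0] == pytest.approx(
            1.23228, abs=5e-5
        )

    def test_trace_reproduces_simulated_npq(self, panel_params):
        tr = simulate_trace(panel_params, noise_sd=0.0)
        light = tr[tr["phase"] == "light"]
        npq = (light["Fm"] - light["Fm_prime"]) / light["Fm_prime"]
        expected = npq_induction(
            light["time_min"].to_numpy(), panel_params["a_npq_i"], panel_params["k_ind"]
        )
        np.testing.assert_allclose(npq, expected, rtol=1e-12)

    def test_asymptote_is_amplitude(self, panel_params):
        t = np.array([1e3])
        assert npq_induction(t, 2.8, 0.58)[0] == pytest.approx(2.8, rel=1e-12)

    def test_same_seed_bit_identical(self, panel_params):
        a = simulate_trace(panel_params, noise_sd=0.05, seed=3)
        b = simulate_trace(panel_params, noise_sd=0.05, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_rate_rejected(self, panel_params):
        bad = dict(panel_params, k_ind=0.0)
        with pytest.raises(ValueError, match="rate"):
            simulate_trace(bad)


class TestGenotypes:
    def test_within_block_dprime_one(self):
        G, v = simulate_genotypes(500, 20, block_size_range=(20, 20), seed=1)
        # nested haplotypes: no recombinant gametes, |D'| = 1 for every pair
        from npqmap.ldblocks import _em_haplotypes, _pair_counts, _dprime

        I, J = np.triu_indices(20, k=1)
        counts = _pair_counts(G, I, J)
        dp = _dprime(_em_haplotypes(counts))[0]
        assert (dp > 0.99).all()

    def test_between_block_r2_near_zero(self):
        G, v = simulate_genotypes(500, 40, block_size_range=(2, 2), seed=2)
        Gc = (G - G.mean(0)) / G.std(0)
        b = v["block"].to_numpy()
        r2 = (Gc.T @ Gc / len(G)) ** 2
        cross = r2[b[:, None] != b[None, :]]
        assert cross.mean() < 0.05

    def test_maf_within_sampling_bounds(self):
        G, v = simulate_genotypes(1000, 200, maf_range=(0.3, 0.5), seed=3)
        maf = np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)
        assert maf.min() >= 0.25 and maf.max() <= 0.5

    def test_positions_strictly_increasing_per_chromosome(self):
        _, v = simulate_genotypes(50, 300, seed=4, n_chrom=3)
        for _, grp in v.groupby("chrom"):
            assert (np.diff(grp["pos"]) > 0).all()

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            simulate_genotypes(50, 1, seed=0)


class TestAnnotation:
    def test_one_gene_per_block_plus_extras(self):
        G, v = simulate_genotypes(50, 100, seed=5)
        genes = simulate_annotation(v, n_extra=30, seed=5)
        nb = v["block"].nunique()
        assert len(genes) == nb + 30
        # block genes span their block's SNPs
        first = v[v["block"] == 0]
        g0 = genes.iloc[0]
        assert g0["start"] <= first["pos"].min() <= first["pos"].max() <= g0["end"]


class TestPhenotypes:
    def _small(self, truth_kw=None, seed=0):
        design = build_design(30, 2, 1, 8, 8, seed=seed)
        G, v = simulate_genotypes(30, 50, seed=seed)
        accs = sorted(design["accession"].unique())
        truth = default_truth(n_accessions=30, seed=seed, **(truth_kw or {}))
        return design, G, accs, truth

    def test_additive_dosage_effect_exact(self):
        design, G, accs, _ = self._small()
        zero = {p: 0.0 for p in KINETIC_PARAMS}
        truth = TruthSpec(
            n_accessions=30,
            genetic_sd=zero,
            gxe_sd=zero,
            set_sd=zero,
            block_sd=zero,
            resid_sd=zero,
            disc_sd=zero,
            spatial_rho_row=0.0,
            spatial_rho_col=0.0,
            causal_snps=[(0, {"a_npq_i": 0.25})],
            seed=1,
        )
        phen = simulate_phenotypes(design, G, accs, truth)
        pv = phen.plot_values
        dos = pd.Series(G[:, 0], index=accs)
        pv["dos"] = pv["accession"].map(dos)
        means = pv.groupby("dos")["a_npq_i"].mean()
        if 2 in means.index and 0 in means.index:
            assert means[2] - means[0] == pytest.approx(0.5, abs=1e-12)

    def test_ar1_row_autocorrelation(self):
        # residual-only field on a 40x24 grid: lag-1 row autocorr ~ rho
        design = build_design(884, 16, 5, 40, 24, seed=2, years=("2017",))
        G, _ = simulate_genotypes(884, 10, seed=2)
        accs = sorted(design["accession"].unique())
        zero = {p: 0.0 for p in KINETIC_PARAMS}
        one = {p: 1.0 for p in KINETIC_PARAMS}
        truth = TruthSpec(
            n_accessions=884,
            genetic_sd=zero,
            gxe_sd=zero,
            set_sd=zero,
            block_sd=zero,
            resid_sd=one,
            disc_sd=zero,
            spatial_rho_row=0.9,
            spatial_rho_col=0.0,
            seed=3,
        )
        phen = simulate_phenotypes(design, G, accs, truth)
        field = phen.plot_values.pivot_table(
            index="row", columns="col", values="a_npq_i"
        ).to_numpy()
        field = field - np.nanmean(field)
        num = np.nansum(field[1:] * field[:-1])
        den = np.nansum(field**2)
        assert num / den == pytest.approx(0.9, abs=0.05)

    def test_unknown_accession_rejected(self):
        design, G, accs, truth = self._small()
        design = design.copy()
        design.loc[design.index[0], "accession"] = "NOPE"
        with pytest.raises(ValueError, match="unknown"):
            simulate_phenotypes(design, G, accs, truth)

    def test_variance_bookkeeping(self):
        # empirical plot variance ~ sum of planted components
        design = build_design(400, 8, 2, 24, 18, seed=4, years=("2017",))
        G, _ = simulate_genotypes(400, 10, seed=4)
        accs = sorted(design["accession"].unique())
        sd = dict(
            genetic_sd=0.3, gxe_sd=0.0, set_sd=0.1, block_sd=0.1, resid_sd=0.4
        )
        comp = {
            k: {p: v for p in KINETIC_PARAMS} for k, v in sd.items()
        }
        truth = TruthSpec(
            n_accessions=400,
            disc_sd={p: 0.0 for p in KINETIC_PARAMS},
            spatial_rho_row=0.0,
            spatial_rho_col=0.0,
            seed=5,
            **comp,
        )
        phen = simulate_phenotypes(design, G, accs, truth)
        total = phen.plot_values["a_npq_i"].var()
        expected = sum(v**2 for v in sd.values())
        assert total == pytest.approx(expected, rel=0.25)


class TestExpression:
    def test_no_factors_gives_uncorrelated_genes(self):
        lines = [f"L{i}" for i in range(300)]
        E, _ = simulate_expression(lines, 50, 0, sparse_fraction=0.0, seed=1)
        C = np.corrcoef(np.log(E.to_numpy()), rowvar=False)
        off = C[np.triu_indices(50, k=1)]
        assert abs(off.mean()) < 0.02

    def test_sparse_gene_below_half_removed_by_filter(self):
        from npqmap.twas import filter_expression

        lines = [f"L{i}" for i in range(229)]
        E, truth = simulate_expression(lines, 200, 2, sparse_fraction=0.3, seed=2)
        below = [
            g for g, f in truth["expressed_frac"].items() if f < 0.5
        ]
        kept, _ = filter_expression(E)
        for g in below:
            assert E.columns[g] not in kept.columns

    def test_causal_latent_drives_expression(self):
        lines = [f"L{i}" for i in range(200)]
        lat = draw_causal_gene_latents(lines, [3], seed=4)
        E, _ = simulate_expression(lines, 20, 2, causal_latents=lat, seed=5)
        r = np.corrcoef(np.log(E.iloc[:, 3]), lat[3])[0, 1]
        assert r > 0.85

    def test_out_of_range_causal_gene_rejected(self):
        lines = [f"L{i}" for i in range(50)]
        lat = draw_causal_gene_latents(lines, [99], seed=0)
        with pytest.raises(IndexError):
            simulate_expression(lines, 20, 2, causal_latents=lat, seed=0)

    def test_seed_determinism(self):
        lines = [f"L{i}" for i in range(40)]
        a, _ = simulate_expression(lines, 30, 3, seed=9)
        b, _ = simulate_expression(lines, 30, 3, seed=9)
        pd.testing.assert_frame_equal(a, b)
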