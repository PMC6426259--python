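"""Synthetic cohort generator: taxonomy, abundance tables, host data."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from casebias.models import CausalModelSpec, nb_size_for_zero_frac
from casebias.synthetic import (TABLE1_FREQUENCIES, embed_causal_structure,
                                sample_abundance_table, sample_host_data)
from casebias.taxonomy import RANKS, build_taxonomy


class TestBuildTaxonomy:
    def test_default_counts_give_168_nodes(self):
        tax = build_taxonomy([6, 12, 17, 36, 63, 34], seed=0)
        assert len(tax) == 168
        assert len(tax.ids_at_rank("genus")) == 63

    def test_single_lineage_chain(self):
        tax = build_taxonomy([1] * 6, seed=0)
        assert len(tax) == 6
        # every node chains to the unique phylum
        species = tax.ids_at_rank("species")[0]
        assert len(tax.lineage(species)) == 6

    def test_same_seed_reproduces(self):
        a = build_taxonomy(seed=11)
        b = build_taxonomy(seed=11)
        assert a.nodes == b.nodes

    def test_parent_is_one_rank_up(self):
        tax = build_taxonomy(seed=2)
        for node in tax.nodes.values():
            if node.rank != "phylum":
                parent = tax.nodes[node.parent]
                assert RANKS.index(parent.rank) == RANKS.index(node.rank) - 1

    @pytest.mark.parametrize("bad", [[5, 5], [1, 2, 3, 4, 5, 0], [2.5] * 6])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            build_taxonomy(bad, seed=0)


class TestAbundanceTable:
    def test_values_bounded_and_hierarchy_consistent(self, small_taxonomy):
        table = sample_abundance_table(small_taxonomy, 40, seed=1)
        vals = table.values.to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1
        table.check_hierarchy()  # children <= parent, rank sums <= 1

    def test_zero_target_zero_gives_positive_leaves(self, small_taxonomy):
        table = sample_abundance_table(small_taxonomy, 30,
                                       target_zero_fracs=0.0, seed=2)
        for leaf in small_taxonomy.leaves():
            assert (table.values[leaf] > 0).all()

    def test_zero_fraction_calibration(self):
        """NB dispersion tuned to the target reproduces the zero fraction."""
        tax = build_taxonomy([1] * 6, seed=0)
        table = sample_abundance_table(tax, 10_000, target_zero_fracs=0.50,
                                       seed=3)
        species = tax.ids_at_rank("species")[0]
        observed = float((table._own_counts[species] == 0).mean())
        assert abs(observed - 0.50) < 0.02

    def test_nb_zero_probability_roundtrip(self):
        size, clamped = nb_size_for_zero_frac(mean=10.0, zero_frac=0.4)
        assert not clamped
        assert (size / (size + 10.0)) ** size == pytest.approx(0.4, abs=1e-9)
        _, clamped = nb_size_for_zero_frac(mean=10.0, zero_frac=1e-6)
        assert clamped  # below the Poisson floor exp(-10)

    def test_same_seed_reproduces(self, small_taxonomy):
        a = sample_abundance_table(small_taxonomy, 10, seed=9)
        b = sample_abundance_table(small_taxonomy, 10, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_bad_targets_rejected(self, small_taxonomy):
        with pytest.raises(ValueError):
            sample_abundance_table(small_taxonomy, 5, target_zero_fracs=0.99)


class TestHostData:
    def test_marginal_frequencies_calibrate(self):
        cohort = sample_host_data(10_000, 0, seed=4)
        meta = cohort.metadata
        for col, target in [("smoking", 0.214), ("treat_antitnf", 0.495)]:
            se = np.sqrt(target * (1 - target) / 10_000)
            assert abs(meta[col].mean() - target) < 3 * se

    def test_zero_frequency_gives_all_zero(self):
        cohort = sample_host_data(500, 0, {"smoking": 0.0}, seed=1)
        assert (cohort.metadata["smoking"] == 0).all()

    def test_controls_lack_treatment_and_subtype(self):
        cohort = sample_host_data(20, 20, seed=6)
        controls = cohort.metadata["d"] == 0
        assert cohort.metadata.loc[controls, "subtype"].isna().all()
        assert cohort.metadata.loc[controls, "treat_5asa"].isna().all()
        cases = ~controls
        assert set(cohort.metadata.loc[cases, "subtype"]) <= {"CD", "UC"}

    def test_age_distribution(self):
        meta = sample_host_data(5_000, 0, seed=2).metadata
        assert meta["age"].min() >= 18
        assert abs(meta["age"].mean() - 40.6) < 1.0

    def test_unknown_frequency_key_rejected(self):
        with pytest.raises(ValueError):
            sample_host_data(10, 0, {"coffee": 0.5})


class TestEmbedCausalStructure:
    def test_empty_assignment_leaves_disease_independent(self, small_taxonomy):
        table = sample_abundance_table(small_taxonomy, 4_000, seed=1)
        cohort = sample_host_data(2_000, 2_000, seed=1)
        table.values.index = cohort.metadata.index
        table._own_counts.index = cohort.metadata.index
        out = embed_causal_structure(table, cohort, {}, seed=3)
        d = out.metadata["d"].to_numpy(dtype=float)
        for tid in list(table.values.columns)[:6]:
            v = table.values[tid].to_numpy()
            if v.std() > 0:
                assert abs(np.corrcoef(v, d)[0, 1]) < 0.06

    def test_mediation_assignment_induces_negative_association(self, small_taxonomy):
        table = sample_abundance_table(small_taxonomy, 6_000,
                                       target_zero_fracs=0.1, seed=2)
        cohort = sample_host_data(3_000, 3_000, seed=2)
        table.values.index = cohort.metadata.index
        table._own_counts.index = cohort.metadata.index
        taxon = small_taxonomy.ids_at_rank("genus")[0]
        spec = CausalModelSpec("a", beta=-0.5, omega_b=-0.5, prevalence=0.5)
        out = embed_causal_structure(table, cohort, {taxon: ("ATG16L1", spec)},
                                     seed=4)
        g = out.locus_dosage("ATG16L1", "dosage").to_numpy()
        v = table.values[taxon].to_numpy()
        r = np.corrcoef(g, v)[0, 1]
        assert r < -0.05  # large-n sign oracle for beta < 0
        # disease depends on the taxon through omega_b < 0
        d = out.metadata["d"].to_numpy(dtype=float)
        assert np.corrcoef(v, d)[0, 1] < -0.05

    def test_unknown_taxon_rejected(self, small_cohort):
        table, cohort = small_cohort
        spec = CausalModelSpec("a", beta=-0.5, omega_b=-0.5)
        with pytest.raises(ValueError):
            embed_causal_structure(table, cohort, {"nope": ("NOD2", spec)})
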