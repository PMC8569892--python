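"""Rarefaction, relative abundance, retention filters, enrichment calls."""

import numpy as np
import pandas as pd
import pytest

import thermonet as tn
from thermonet.preprocess import OTUTable


def _table(rows, otus, meta_rows):
    meta = pd.DataFrame(meta_rows, columns=["lake", "habitat"],
                        index=pd.Index([r[0] for r in rows], name="sample"))
    data = pd.DataFrame([r[1] for r in rows], index=meta.index, columns=otus)
    return OTUTable(data, meta)


class TestRarefy:
    def test_sample_at_exact_depth_unchanged(self):
        t = _table([("s1", [100, 0, 50])], ["a", "b", "c"], [("L1", "sediment")])
        out = tn.rarefy(t, 150, seed=0)
        assert list(out.data.loc["s1"]) == [100, 0, 50]

    def test_sample_below_depth_dropped(self):
        t = _table([("s1", [100, 0, 50]), ("s2", [100, 100, 0])],
                   ["a", "b", "c"], [("L1", "sediment"), ("L1", "water")])
        out = tn.rarefy(t, 151, seed=0)
        assert list(out.sample_ids) == ["s2"]

    def test_all_below_depth_errors(self):
        t = _table([("s1", [1, 1, 1])], ["a", "b", "c"], [("L1", "sediment")])
        with pytest.raises(ValueError, match="no samples at depth"):
            tn.rarefy(t, 100, seed=0)

    def test_hypergeometric_expectation(self):
        """Subsampling [1000, 1000] to 1000 reads leaves on average 500
        of the first OTU (within 3 SE over 500 seeds)."""
        t = _table([("s1", [1000, 1000])], ["a", "b"], [("L1", "sediment")])
        draws = np.array([
            tn.rarefy(t, 1000, seed=s).data.loc["s1", "a"] for s in range(500)
        ])
        # variance of the hypergeometric: n*K/N*(1-K/N)*(N-n)/(N-1)
        var = 1000 * 0.5 * 0.5 * (2000 - 1000) / (2000 - 1)
        se = np.sqrt(var / 500)
        assert abs(draws.mean() - 500) < 3 * se

    def test_deterministic_under_seed(self):
        t = _table([("s1", [400, 300, 300])], ["a", "b", "c"], [("L1", "water")])
        a = tn.rarefy(t, 500, seed=42).data
        b = tn.rarefy(t, 500, seed=42).data
        assert a.equals(b)

    def test_rejects_relative_table(self, tiny_table):
        ra = tn.relative_abundance(tiny_table)
        with pytest.raises(ValueError):
            tn.rarefy(ra, 10, seed=0)


class TestRelativeAbundance:
    def test_simple_division(self):
        t = _table([("s1", [10, 30, 60])], ["a", "b", "c"], [("L1", "water")])
        out = tn.relative_abundance(t)
        assert list(out.data.loc["s1"]) == [0.1, 0.3, 0.6]
        assert out.is_relative

    def test_rows_sum_to_one(self, small_community):
        _, table, _, _ = small_community
        ra = tn.relative_abundance(table)
        assert np.allclose(ra.data.sum(axis=1), 1.0)

    def test_detection_threshold_at_standard_depth(self):
        """At a depth of 27,890 reads, 3 reads clear the 0.01% abundance
        threshold and 2 reads do not."""
        depth = 27_890
        assert 3 / depth > 1e-4
        assert 2 / depth < 1e-4
        assert np.isclose(3 / depth, 1.0756e-4, rtol=1e-4)

    def test_zero_total_sample_errors(self):
        t = _table([("s1", [0, 0])], ["a", "b"], [("L1", "water")])
        with pytest.raises(ValueError, match="zero total"):
            tn.relative_abundance(t)

    def test_rarefied_entries_are_multiples_of_inverse_depth(self):
        t = _table([("s1", [700, 200, 100]), ("s2", [100, 400, 600])],
                   ["a", "b", "c"], [("L1", "sediment"), ("L1", "water")])
        depth = 300
        ra = tn.relative_abundance(tn.rarefy(t, depth, seed=1))
        mult = ra.data.to_numpy() * depth
        assert np.allclose(mult, np.round(mult))


def _paired_table(n_lakes, presence_lakes, ra_sed=2e-4, ra_wat=2e-4):
    """One focal OTU present in both habitats of the first
    ``presence_lakes`` lakes, plus filler OTUs.  ``ra_sed``/``ra_wat``
    set the focal OTU's habitat-wise MEAN relative abundance (the
    quantity the filters threshold), spread over the present samples."""
    rows, meta = [], []
    for i in range(n_lakes):
        present = i < presence_lakes
        for hab, mean_ra in (("sediment", ra_sed), ("water", ra_wat)):
            val = mean_ra * n_lakes / presence_lakes if (present and presence_lakes) \
                else 0.0
            rows.append((f"L{i}_{hab}", [val, 0.0999, 1 - val - 0.0999]))
            meta.append((f"L{i}", hab))
    t = _table(rows, ["focal", "other", "bulk"], meta)
    t.is_relative = True
    return t


class TestMetacommunityFilter:
    def test_presence_in_eight_lakes_retained(self):
        t = _paired_table(23, presence_lakes=8)
        assert "focal" in tn.filter_metacommunity(t)

    def test_presence_in_seven_lakes_excluded(self):
        t = _paired_table(23, presence_lakes=7)
        assert "focal" not in tn.filter_metacommunity(t)

    def test_requires_joint_presence_within_a_lake(self):
        """Present in water everywhere but never in sediment: excluded."""
        t = _paired_table(23, presence_lakes=23, ra_sed=0.0)
        assert "focal" not in tn.filter_metacommunity(t)

    def test_mean_abundance_must_exceed_threshold_strictly(self):
        # mean RA over each habitat's 23 samples is exactly 1e-4
        t = _paired_table(23, presence_lakes=23, ra_sed=23e-4 / 23 * 0,
                          ra_wat=1e-4)
        # focal present in water only in every lake -> joint presence 0
        assert "focal" not in tn.filter_metacommunity(t)
        t2 = _paired_table(23, presence_lakes=23, ra_sed=1e-4, ra_wat=1e-4)
        assert "focal" not in tn.filter_metacommunity(t2)
        t3 = _paired_table(23, presence_lakes=23, ra_sed=1.01e-4, ra_wat=1e-4)
        assert "focal" in tn.filter_metacommunity(t3)

    def test_result_subset_of_jointly_present_otus(self, small_community):
        _, table, _, _ = small_community
        ra = tn.relative_abundance(table)
        kept = tn.filter_metacommunity(ra)
        sed = ra.data.loc[ra.samples_of("sediment")].sum(axis=0)
        wat = ra.data.loc[ra.samples_of("water")].sum(axis=0)
        for otu in kept:
            assert sed[otu] > 0 and wat[otu] > 0

    def test_idempotent(self, small_community):
        _, table, _, _ = small_community
        ra = tn.relative_abundance(table)
        kept = tn.filter_metacommunity(ra)
        again = tn.filter_metacommunity(ra.subset_otus(kept))
        assert set(again) == set(kept)


class TestHabitatFilter:
    def test_boundary_prevalence_and_abundance(self):
        t = _paired_table(23, presence_lakes=8, ra_wat=1.5e-4)
        assert "focal" in tn.filter_habitat(t, "water")
        t2 = _paired_table(23, presence_lakes=7, ra_wat=1.5e-4)
        assert "focal" not in tn.filter_habitat(t2, "water")

    def test_mean_exactly_at_threshold_excluded(self):
        t = _paired_table(23, presence_lakes=23, ra_wat=1e-4)
        assert "focal" not in tn.filter_habitat(t, "water")

    def test_all_zero_otu_excluded(self):
        t = _paired_table(23, presence_lakes=0)
        assert "focal" not in tn.filter_habitat(t, "water")

    def test_unknown_habitat_errors(self, tiny_table):
        ra = tn.relative_abundance(tiny_table)
        with pytest.raises(ValueError, match="habitat"):
            tn.filter_habitat(ra, "soil")

    def test_idempotent(self, small_community):
        _, table, _, _ = small_community
        ra = tn.relative_abundance(table)
        kept = tn.filter_habitat(ra, "water")
        again = tn.filter_habitat(ra.subset_otus(kept), "water")
        assert set(again) == set(kept)


class TestEnrichment:
    def test_large_consistent_difference_called(self):
        rows, meta = [], []
        rng = np.random.default_rng(1)
        for i in range(23):
            base = rng.uniform(0.001, 0.002)
            rows.append((f"L{i}_sediment", [base, 0.5 - base, 0.5]))
            rows.append((f"L{i}_water", [10 * base, 0.5 - 10 * base, 0.5]))
            meta += [(f"L{i}", "sediment"), (f"L{i}", "water")]
        t = _table(rows, ["focal", "other", "bulk"], meta)
        t.is_relative = True
        labels = tn.classify_enrichment(t)
        assert labels.table.loc["focal", "label"] == "water"
        assert labels.table.loc["focal", "p_adjusted"] < 1e-6

    def test_identical_profiles_not_enriched(self, tiny_table):
        ra = tn.relative_abundance(tiny_table)
        same = ra.data.copy()
        # make both habitats identical per lake
        for lake in ra.meta["lake"].unique():
            same.loc[f"{lake}_water"] = same.loc[f"{lake}_sediment"].to_numpy()
        t = OTUTable(same, ra.meta, is_relative=True)
        labels = tn.classify_enrichment(t)
        assert (labels.labels() == "none").all()

    def test_planted_enrichment_recovered(self):
        """With an 8-fold planted enrichment, at least 90% of enriched
        OTUs are labelled with the correct habitat."""
        cfg = tn.SynthConfig(seed=19, enrichment_fold=8.0,
                             n_otus_shared=80, n_otus_sediment=5,
                             n_otus_water=5, depth=27_890)
        table, env, truth = tn.generate_community(cfg)
        ra = tn.relative_abundance(table)
        labels = tn.classify_enrichment(ra)
        planted = {o: h for o, h in truth.enriched_in.items() if h != "none"}
        hits = sum(labels.table.loc[o, "label"] == h for o, h in planted.items())
        assert hits / len(planted) >= 0.9

    def test_labels_partition_the_otu_set(self, small_community):
        _, table, _, _ = small_community
        ra = tn.relative_abundance(table)
        labels = tn.classify_enrichment(ra)
        assert set(labels.table.index) == set(table.otu_ids)
        assert set(labels.labels().unique()) <= {"sediment", "water", "none"}
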