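"""Synthetic-data generators: determinism and internal consistency."""

import numpy as np
import pandas as pd
import pytest

from pubfig.fixtures import (
    BASE_CHANGES,
    DEFAULT_SEED,
    fig1_gallery,
    make_fig1_datasets,
    make_mutation_dataset,
    summarize_mutations,
    write_fixture_files,
)


def _recount(ds):
    """Brute-force recount of every derived summary, straight off the matrices."""
    genes, patients = ds.genes, ds.patients
    pct = {}
    for g in genes:
        hit = sum(
            (ds.snv.loc[g, p] is not None) or (ds.cna.loc[g, p] is not None)
            for p in patients
        )
        pct[g] = 100.0 * hit / len(patients)
    counts = {}
    for p in patients:
        counts[p] = (
            sum(ds.snv.loc[g, p] is not None for g in genes),
            sum(ds.cna.loc[g, p] is not None for g in genes),
        )
    props = {}
    for p in patients:
        total = counts[p][0] + counts[p][1]
        row = {}
        for cls in BASE_CHANGES:
            n_cls = sum(
                ds.snv.loc[g, p] is not None and ds.basechange.loc[g, p] == cls
                for g in genes
            )
            row[cls] = n_cls / total if total else 0.0
        props[p] = row
    return pct, counts, props


class TestMutationDataset:
    def test_zero_rates_give_empty_matrices(self):
        ds = make_mutation_dataset(5, 8, p_snv=0.0, p_cna=0.0, seed=1)
        assert ds.snv.isna().to_numpy().all()
        assert (ds.derived["per_gene_pct"] == 0).all()
        assert (ds.derived["per_patient_counts"].sum(axis=1) == 0).all()

    def test_saturated_snv_rate(self):
        ds = make_mutation_dataset(6, 9, p_snv=1.0, p_cna=0.0, seed=1)
        assert (ds.derived["per_gene_pct"] == 100.0).all()
        assert (ds.derived["per_patient_counts"]["snv"] == 6).all()

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            make_mutation_dataset(2, 2, p_snv=1.5)

    def test_derived_summaries_match_brute_force_recount(self):
        ds = make_mutation_dataset(20, 40, p_snv=0.1, p_cna=0.05, seed=3)
        pct, counts, props = _recount(ds)
        for g in ds.genes:
            assert ds.derived["per_gene_pct"][g] == pytest.approx(pct[g])
        for p in ds.patients:
            got = ds.derived["per_patient_counts"].loc[p]
            assert (got["snv"], got["cna"]) == counts[p]
            for cls in BASE_CHANGES:
                assert ds.derived["basechange_props"].loc[p, cls] == pytest.approx(
                    props[p][cls]
                )

    def test_consistency_relations_hold_over_random_parameterizations(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            ng = int(rng.integers(1, 10))
            np_ = int(rng.integers(1, 14))
            ds = make_mutation_dataset(
                ng, np_,
                p_snv=float(rng.uniform(0, 0.6)),
                p_cna=float(rng.uniform(0, 0.4)),
                seed=int(rng.integers(0, 2**31)),
            )
            snv_mask = ds.snv.notna()
            cna_mask = ds.cna.notna()
            # per-gene percentage definition
            expect_pct = 100 * (snv_mask | cna_mask).sum(axis=1) / np_
            assert np.allclose(ds.derived["per_gene_pct"], expect_pct)
            # per-patient counts definition
            assert (ds.derived["per_patient_counts"]["snv"] == snv_mask.sum(axis=0)).all()
            assert (ds.derived["per_patient_counts"]["cna"] == cna_mask.sum(axis=0)).all()
            # base-change proportions sum to snv_count / total_count
            counts = ds.derived["per_patient_counts"]
            total = counts["snv"] + counts["cna"]
            sums = ds.derived["basechange_props"].sum(axis=1)
            for p in ds.patients:
                expected = counts.loc[p, "snv"] / total[p] if total[p] else 0.0
                assert sums[p] == pytest.approx(expected)
            assert ((ds.derived["basechange_props"] >= 0).to_numpy().all()
                    and (ds.derived["basechange_props"] <= 1).to_numpy().all())

    def test_same_seed_reproduces_dataset(self):
        a = make_mutation_dataset(seed=5)
        b = make_mutation_dataset(seed=5)
        pd.testing.assert_frame_equal(a.snv, b.snv)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)


class TestFig1Datasets:
    def test_same_seed_identical_collections(self):
        a = make_fig1_datasets(7)
        b = make_fig1_datasets(7)
        assert set(a) == set(b)
        for name in a:
            if isinstance(a[name], pd.DataFrame):
                pd.testing.assert_frame_equal(a[name], b[name])
            else:  # dotmap
                assert (a[name].cell_categories == b[name].cell_categories).all()

    def test_manhattan_fixture_p_values_in_domain(self):
        p = make_fig1_datasets(DEFAULT_SEED)["manhattan"]["p_value"]
        assert ((p > 0) & (p <= 1)).all()

    def test_gallery_covers_every_chart_type_with_matching_binding(self):
        gallery = fig1_gallery(DEFAULT_SEED)
        assert len(gallery) == 15
        for name, (spec, _) in gallery.items():
            assert spec.chart_type == name

    def test_written_fixture_files_are_csv(self, tmp_path):
        written = write_fixture_files(tmp_path, seed=1)
        assert "scatterplot" in written and "dotmap_cell" in written
        df = pd.read_csv(written["scatterplot"])
        assert {"x", "y"} <= set(df.columns)
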