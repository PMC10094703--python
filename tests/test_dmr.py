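import numpy as np
import pandas as pd
import pytest

from ssv_meth import (
    GroupContrast,
    call_dmrs,
    max_change_subregion,
    persistence_filter,
    probe_deltas,
)
from ssv_meth.preprocess import MethylationDataset

from conftest import make_dataset
from oracle_dmr import oracle_max_window, oracle_regions, random_fixture


def deltas_fixture(values, positions, chrom="chr1"):
    probe_ids = [f"cg{i:04d}" for i in range(len(values))]
    manifest = pd.DataFrame(
        {"chrom": chrom, "pos": list(positions)},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return pd.Series(values, index=probe_ids, dtype=float), manifest


class TestProbeDeltas:
    def test_identical_group_composition_gives_zero(self):
        row = [0.2, 0.7, 0.5]
        ds = make_dataset([row, row, row, row], [100, 1100, 2100])
        contrast = GroupContrast(("S1", "S2"), ("S3", "S4"))
        d = probe_deltas(ds, contrast)
        assert np.allclose(d.to_numpy(), 0.0)

    def test_arithmetic_example(self):
        # target means {0.1, 0.2}, reference means {0.8, 0.6, 0.7} → −0.55
        beta = [[0.1, 0.5], [0.2, 0.5], [0.8, 0.5], [0.6, 0.5], [0.7, 0.5]]
        ds = make_dataset(beta, [100, 1100])
        d = probe_deltas(ds, GroupContrast(("S1", "S2"), ("S3", "S4", "S5")))
        assert d.iloc[0] == pytest.approx(-0.55)

    def test_matches_bruteforce_loop(self, small_bundle):
        ds = small_bundle["dataset"]
        asn = small_bundle["assignment"]
        target = tuple(asn.index[asn == 2])
        reference = tuple(asn.index[asn != 2])
        d = probe_deltas(ds, GroupContrast(target, reference))
        for p in list(ds.beta.columns)[::101]:
            t = sum(ds.beta.loc[s, p] for s in target) / len(target)
            r = sum(ds.beta.loc[s, p] for s in reference) / len(reference)
            assert d[p] == pytest.approx(t - r, abs=1e-12)

    def test_missing_sample_rejected(self):
        ds = make_dataset([[0.5, 0.5]] * 2, [100, 1100])
        with pytest.raises(KeyError):
            probe_deltas(ds, GroupContrast(("S1",), ("NOPE",)))

    def test_contrast_groups_must_be_disjoint_and_nonempty(self):
        with pytest.raises(ValueError):
            GroupContrast(("S1",), ("S1", "S2"))
        with pytest.raises(ValueError):
            GroupContrast((), ("S1",))


class TestCallDmrs:
    def test_three_probe_chain(self):
        d, man = deltas_fixture([-0.3, -0.35, -0.25], [100, 600, 1400])
        regions = call_dmrs(d, man)
        assert len(regions) == 1
        (r,) = regions
        assert r.probe_ids == ("cg0000", "cg0001", "cg0002")
        assert r.mean_delta == pytest.approx(-0.30)
        assert r.direction == "hypo"
        assert (r.start, r.end) == (100, 1400)

    def test_isolated_single_probe_is_not_a_region(self):
        d, man = deltas_fixture([0.0, -0.4, 0.0], [100, 2000, 4000])
        assert call_dmrs(d, man) == []

    @pytest.mark.parametrize(
        "gap,n_expected", [(900, 1), (1000, 1), (1001, 0), (1500, 0)]
    )
    def test_gap_rule_boundary(self, gap, n_expected):
        d, man = deltas_fixture([-0.3, -0.3], [1000, 1000 + gap])
        assert len(call_dmrs(d, man)) == n_expected

    def test_sign_change_splits_chains(self):
        d, man = deltas_fixture([-0.3, -0.3, 0.3, 0.3],
                                [100, 600, 1100, 1600])
        regions = call_dmrs(d, man)
        assert [r.direction for r in regions] == ["hypo", "hyper"]
        assert [r.probe_ids for r in regions] == [
            ("cg0000", "cg0001"), ("cg0002", "cg0003")
        ]

    def test_unsorted_manifest_rejected(self):
        d, man = deltas_fixture([-0.3, -0.3], [500, 100])
        man_bad = man.iloc[::1]
        with pytest.raises(ValueError, match="not sorted"):
            call_dmrs(d, man_bad)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(10)
        for _ in range(40):
            deltas, manifest = random_fixture(rng)
            called = call_dmrs(deltas, manifest)
            expected = oracle_regions(deltas, manifest)
            assert [(r.chrom, r.probe_ids) for r in called] == [
                (c, ids) for c, ids, _ in expected
            ]
            for r, (_, _, mean) in zip(called, expected):
                assert r.mean_delta == pytest.approx(mean, abs=1e-12)

    def test_lower_threshold_keeps_existing_footprints(self):
        """On direction-consistent data, relaxing the probe threshold only
        grows or merges regions, never loses a called footprint."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            deltas, manifest = random_fixture(rng)
            deltas = -deltas.abs()  # consistent hypo direction
            strict = call_dmrs(deltas, manifest, delta_threshold=0.3)
            relaxed = call_dmrs(deltas, manifest, delta_threshold=0.2)
            for r in strict:
                assert any(set(r.probe_ids) <= set(r2.probe_ids)
                           for r2 in relaxed)

    def test_direction_symmetry_under_beta_inversion(self, small_bundle):
        """Negating β (β → 1−β) swaps hypo and hyper calls exactly."""
        ds = small_bundle["dataset"]
        asn = small_bundle["assignment"]
        contrast = GroupContrast(tuple(asn.index[asn == 2]),
                                 tuple(asn.index[asn != 2]))
        inverted = MethylationDataset(beta=1 - ds.beta, probes=ds.probes.copy())
        a = call_dmrs(probe_deltas(ds, contrast), ds.probes)
        b = call_dmrs(probe_deltas(inverted, contrast), inverted.probes)
        assert [(r.chrom, r.probe_ids, r.direction) for r in a] == [
            (r.chrom, r.probe_ids,
             "hypo" if r.direction == "hyper" else "hyper") for r in b
        ]
        for ra, rb in zip(a, b):
            assert ra.mean_delta == pytest.approx(-rb.mean_delta, abs=1e-12)


class TestMaxChangeSubregion:
    def test_best_window_located(self):
        d, man = deltas_fixture([-0.25, -0.35, -0.4, -0.2],
                                [100, 600, 1100, 1600])
        (dmr,) = call_dmrs(d, man)
        updated = max_change_subregion(dmr, d, man, threshold=0.3)
        assert updated is not None
        assert updated.max_subregion.probe_ids == ("cg0001", "cg0002")
        assert updated.max_subregion.mean_delta == pytest.approx(-0.375)

    def test_uniform_quarter_delta_rejected_at_point_three(self):
        d, man = deltas_fixture([-0.25, -0.25, -0.25], [100, 600, 1100])
        (dmr,) = call_dmrs(d, man)
        assert max_change_subregion(dmr, d, man, threshold=0.3) is None

    def test_two_probe_region_has_single_window(self):
        d, man = deltas_fixture([-0.35, -0.31], [100, 600])
        (dmr,) = call_dmrs(d, man)
        updated = max_change_subregion(dmr, d, man, threshold=0.3)
        assert updated.max_subregion.probe_ids == dmr.probe_ids
        d2, man2 = deltas_fixture([-0.28, -0.26], [100, 600])
        (dmr2,) = call_dmrs(d2, man2)
        assert max_change_subregion(dmr2, d2, man2, threshold=0.3) is None

    def test_matches_exhaustive_window_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            deltas, manifest = random_fixture(rng)
            for dmr in call_dmrs(deltas, manifest):
                updated = max_change_subregion(dmr, deltas, manifest)
                best = oracle_max_window(deltas, dmr.probe_ids)
                if abs(best) > 0.3:
                    assert updated is not None
                    assert updated.max_subregion.mean_delta == pytest.approx(
                        best, abs=1e-12
                    )
                    assert set(updated.max_subregion.probe_ids) <= set(
                        dmr.probe_ids
                    )
                    assert abs(updated.max_subregion.mean_delta) >= abs(
                        dmr.mean_delta
                    ) - 1e-12
                else:
                    assert updated is None


class TestPersistenceFilter:
    def _planted(self, small_bundle):
        ds = small_bundle["dataset"]
        asn = small_bundle["assignment"]
        contrast = GroupContrast(tuple(asn.index[asn == 2]),
                                 tuple(asn.index[asn != 2]))
        deltas = probe_deltas(ds, contrast)
        return ds, asn, deltas, call_dmrs(deltas, ds.probes)

    def test_single_other_subgroup_equals_pooled_decision(self):
        beta = [[0.1, 0.1], [0.15, 0.1], [0.8, 0.75], [0.7, 0.8]]
        ds = make_dataset(beta, [100, 600])
        asn = pd.Series([1, 1, 2, 2], index=["S1", "S2", "S3", "S4"])
        contrast = GroupContrast(("S1", "S2"), ("S3", "S4"))
        deltas = probe_deltas(ds, contrast)
        (dmr,) = call_dmrs(deltas, ds.probes)
        updated = max_change_subregion(dmr, deltas, ds.probes)
        pooled_pass = updated is not None
        ok, table = persistence_filter(dmr, ds, asn, target_subgroup=1)
        assert ok == pooled_pass
        assert len(table) == 1

    def test_fails_when_one_comparison_lacks_signal(self):
        # subgroup 1 low, subgroup 2 high, subgroup 3 low: hypomethylation
        # of group 1 does not persist against group 3
        beta = [[0.1, 0.1], [0.1, 0.12], [0.9, 0.85], [0.88, 0.9],
                [0.12, 0.1], [0.1, 0.14]]
        ds = make_dataset(beta, [100, 600])
        asn = pd.Series([1, 1, 2, 2, 3, 3],
                        index=[f"S{i + 1}" for i in range(6)])
        contrast = GroupContrast(("S1", "S2"), ("S3", "S4", "S5", "S6"))
        deltas = probe_deltas(ds, contrast)
        (dmr,) = call_dmrs(deltas, ds.probes)
        ok, table = persistence_filter(dmr, ds, asn, target_subgroup=1)
        assert not ok
        assert len(table) == 2
        assert table.set_index("other_subgroup")["passed"][2]
        assert not table.set_index("other_subgroup")["passed"][3]

    def test_planted_ssv_regions_persist_background_does_not(
            self, small_bundle):
        ds, asn, deltas, dmrs = self._planted(small_bundle)
        truth = small_bundle["truth"]
        ssv_spans = [(c, s, e) for _, c, s, e, _ in truth.ssv_genes]
        found_ssv = 0
        for dmr in dmrs:
            if dmr.direction != "hypo":
                continue
            updated = max_change_subregion(dmr, deltas, ds.probes)
            if updated is None:
                continue
            ok, _ = persistence_filter(updated, ds, asn, target_subgroup=2)
            is_planted_ssv = any(
                c == dmr.chrom and s <= dmr.start and dmr.end <= e
                for c, s, e in ssv_spans
            )
            if is_planted_ssv:
                assert ok
                found_ssv += 1
        assert found_ssv == len(ssv_spans)
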