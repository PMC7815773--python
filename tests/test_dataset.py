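"""Band categorization, 1:5 assembly, and the synthetic-data generators."""

from __future__ import annotations

import numpy as np
import pytest

from dockface import (CategoryScheme, DecoyQuality, DimerComplex,
                      assemble_examples, categorize, generate_decoys,
                      make_toy_dimer, residue_contacts)
from dockface.dataset import FNAT_BANDS, IRMSD_BANDS, _in_interval
from dockface.interface import InterfaceDefinition, interface_residues
from dockface.structure import STANDARD_RESIDUES, coords_of


def q(fnat=1.0, irmsd=0.0):
    return DecoyQuality(fnat, irmsd, 10, 20)


class TestCategorize:
    @pytest.mark.parametrize("fnat_value,band,expected", [
        (0.90, "high", "native"),       # above the 0.8 native cutoff
        (0.90, "mixed", "native"),
        (0.20, "high", "non_native"),
        (0.25, "high", "non_native"),   # boundary belongs to high
        (0.25, "moderate", "excluded"),
        (0.50, "moderate", "non_native"),
        (0.50, "weak", "excluded"),
        (0.80, "weak", "non_native"),
        (0.80, "mixed", "non_native"),
        (0.60, "moderate", "excluded"),
        (0.00, "high", "non_native"),   # zero conserved contacts
        (0.60, "weak", "non_native"),
    ])
    def test_fnat_scheme(self, fnat_value, band, expected):
        scheme = CategoryScheme("fnat", band)
        assert categorize(q(fnat=fnat_value), scheme) == expected

    @pytest.mark.parametrize("irmsd_value,band,expected", [
        (4.2, "high", "native"),
        (5.0, "weak", "non_native"),    # 5 A is already non-native
        (5.0, "mixed", "non_native"),
        (5.0, "high", "excluded"),
        (10.0, "moderate", "non_native"),
        (10.0, "weak", "excluded"),
        (15.0, "high", "non_native"),
        (15.0, "moderate", "excluded"),
        (40.0, "high", "non_native"),
        (40.0, "mixed", "non_native"),
    ])
    def test_irmsd_scheme(self, irmsd_value, band, expected):
        scheme = CategoryScheme("irmsd", band)
        assert categorize(q(irmsd=irmsd_value), scheme) == expected

    def test_every_value_gets_exactly_one_label(self):
        labels = {"native", "non_native", "excluded"}
        for band in ("high", "moderate", "weak", "mixed"):
            for x in np.linspace(0, 1, 101):
                assert categorize(q(fnat=x),
                                  CategoryScheme("fnat", band)) in labels
            for x in np.linspace(0, 40, 161):
                assert categorize(q(irmsd=x),
                                  CategoryScheme("irmsd", band)) in labels

    def test_narrow_bands_partition_non_native_range(self):
        for x in np.linspace(0.0, 0.8, 1601):
            hits = [b for b in ("high", "moderate", "weak")
                    if _in_interval(x, FNAT_BANDS[b])]
            assert len(hits) == 1
        for x in np.linspace(5.0, 40.0, 1601):
            hits = [b for b in ("high", "moderate", "weak")
                    if _in_interval(x, IRMSD_BANDS[b])]
            assert len(hits) == 1

    def test_bands_disjoint_from_native_region(self):
        assert categorize(q(fnat=0.81), CategoryScheme("fnat",
                                                       "mixed")) == "native"
        assert categorize(q(irmsd=4.99),
                          CategoryScheme("irmsd", "mixed")) == "native"

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            CategoryScheme("fnat", "extreme")
        with pytest.raises(ValueError):
            CategoryScheme("lrmsd", "high")


@pytest.fixture(scope="module")
def tiny_ref():
    return make_toy_dimer(12, seed=3)


def fake_decoys(ref, qualities):
    return [(DimerComplex(ref.receptor, ref.ligand, label=f"fake{i}"), qq)
            for i, qq in enumerate(qualities)]


class TestAssembleExamples:
    def test_two_native_ten_non_native(self, tiny_ref):
        qualities = [q(fnat=0.95), q(fnat=0.85), q(fnat=0.9)] + \
            [q(fnat=0.01 * i) for i in range(15)]   # 15 in the high band
        decoys = fake_decoys(tiny_ref, qualities)
        cache = {}
        ls = assemble_examples(tiny_ref, decoys,
                               CategoryScheme("fnat", "high"), seed=5,
                               feature_params={"sasa_params":
                                               {"n_points": 60}},
                               feature_cache=cache)
        assert ls.counts == {"native": 2, "non_native": 10}
        assert ls.flags == []

    def test_best_native_decoy_chosen(self, tiny_ref):
        qualities = [q(fnat=0.85), q(fnat=0.99)] + \
            [q(fnat=0.1)] * 10
        labeled = [categorize(qq, CategoryScheme("fnat", "high"))
                   for qq in qualities]
        assert labeled[:2] == ["native", "native"]
        # the 0.99 decoy must be the second native (best-by-metric rule)
        decoys = fake_decoys(tiny_ref, qualities)
        ls = assemble_examples(tiny_ref, decoys,
                               CategoryScheme("fnat", "high"), seed=1,
                               feature_params={"sasa_params":
                                               {"n_points": 60}})
        assert ls.counts["native"] == 2

    def test_strict_mode_errors(self, tiny_ref):
        no_native = fake_decoys(tiny_ref, [q(fnat=0.1)] * 12)
        with pytest.raises(ValueError, match="native cutoff"):
            assemble_examples(tiny_ref, no_native,
                              CategoryScheme("fnat", "high"), seed=1)
        short_band = fake_decoys(tiny_ref,
                                 [q(fnat=0.9)] + [q(fnat=0.1)] * 4)
        with pytest.raises(ValueError, match="band"):
            assemble_examples(tiny_ref, short_band,
                              CategoryScheme("fnat", "high"), seed=1)

    def test_lenient_mode_flags(self, tiny_ref):
        short = fake_decoys(tiny_ref, [q(fnat=0.9)] + [q(fnat=0.1)] * 4)
        ls = assemble_examples(tiny_ref, short,
                               CategoryScheme("fnat", "high"), seed=1,
                               strict=False,
                               feature_params={"sasa_params":
                                               {"n_points": 60}})
        assert "short_non_native_pool" in ls.flags
        assert ls.counts["non_native"] == 4

    def test_seeded_selection_is_deterministic(self, tiny_ref):
        decoys = fake_decoys(tiny_ref,
                             [q(fnat=0.9)] + [q(fnat=0.1)] * 20)
        kw = dict(scheme=CategoryScheme("fnat", "high"), seed=11,
                  feature_params={"sasa_params": {"n_points": 60}})
        a = assemble_examples(tiny_ref, decoys, **kw)
        b = assemble_examples(tiny_ref, decoys, **kw)
        for (fva, la), (fvb, lb) in zip(a.entries, b.entries):
            assert la == lb
            np.testing.assert_array_equal(fva.values, fvb.values)


class TestMakeToyDimer:
    def test_deterministic(self):
        a = make_toy_dimer(15, seed=9)
        b = make_toy_dimer(15, seed=9)
        np.testing.assert_array_equal(coords_of(a.atoms),
                                      coords_of(b.atoms))

    def test_two_chains_standard_residues_heavy_atoms(self, toy30):
        assert toy30.receptor_chain_id != toy30.ligand_chain_id
        assert all(a.residue_name in STANDARD_RESIDUES
                   for a in toy30.atoms)
        assert all(a.element in ("C", "N", "O") for a in toy30.atoms)

    def test_interface_quota_across_seeds(self):
        for seed in range(4):
            d = make_toy_dimer(20, seed=seed)
            r, l = interface_residues(
                d, InterfaceDefinition("contact_distance", 10.0))
            assert (len(r) + len(l)) / 40 >= 0.2
            assert len(residue_contacts(d)) >= 8

    def test_backbone_geometry(self, toy30):
        cas = [a for a in toy30.receptor if a.atom_name == "CA"]
        steps = [np.linalg.norm(b.coord - a.coord)
                 for a, b in zip(cas, cas[1:])]
        assert all(abs(s - 3.8) < 1e-6 for s in steps)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_toy_dimer(3, seed=1)


class TestGenerateDecoys:
    def test_poses_are_clash_free(self, toy30, ladder30):
        from scipy.spatial import cKDTree
        for pose, _ in ladder30:
            d, _i = cKDTree(coords_of(pose.receptor)).query(
                coords_of(pose.ligand), k=1)
            assert d.min() >= 2.0

    def test_deterministic(self, toy30):
        a = generate_decoys(toy30, 5, seed=4)
        b = generate_decoys(toy30, 5, seed=4)
        for (pa, qa), (pb, qb) in zip(a, b):
            np.testing.assert_array_equal(coords_of(pa.atoms),
                                          coords_of(pb.atoms))
            assert qa.fnat == qb.fnat

    def test_far_translation_kills_fnat(self, toy30):
        from dockface import rigid_transform
        far = DimerComplex(toy30.receptor,
                           rigid_transform(toy30.ligand, np.eye(3),
                                           np.array([0, 0, 25.0])))
        from dockface import fnat
        assert fnat(toy30, far) == 0.0

    def test_stratified_fills_all_bands(self, ladder30):
        fn = np.array([qq.fnat for _, qq in ladder30])
        ir = np.array([qq.irmsd for _, qq in ladder30])
        for band in ("high", "moderate", "weak"):
            assert sum(1 for x in fn if x <= 0.8
                       and _in_interval(x, FNAT_BANDS[band])) >= 3
            assert sum(1 for x in ir if x >= 5.0
                       and _in_interval(x, IRMSD_BANDS[band])) >= 3
        assert ((fn > 0.8) | (ir < 5.0)).sum() >= 3

    def test_no_interface_reference_rejected(self, toy30):
        from dockface import rigid_transform
        far = DimerComplex(toy30.receptor,
                           rigid_transform(toy30.ligand, np.eye(3),
                                           np.array([500.0, 0, 0])))
        with pytest.raises(ValueError):
            generate_decoys(far, 5, seed=1)
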