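import io

import pytest
from hypothesis import given, settings, strategies as st

from ionslab.materials import (
    ELEMENTS,
    Material,
    Layer,
    Phantom,
    builtin_phantom,
    load_phantom,
    number_densities,
    phantom_table,
    save_phantom,
)

TABLE_SYMBOLS = ["H", "C", "N", "O", "S", "Cl", "Na", "K", "P", "Mg", "Ca", "Fe", "F"]


class TestFixtures:
    @pytest.mark.parametrize("variant", ["tissue", "biomaterial"])
    def test_ten_layers_and_unit_fractions(self, variant):
        ph = builtin_phantom(variant)
        assert len(ph.layers) == 10
        for layer in ph.layers:
            total = sum(e.atomic_fraction for e in layer.material.elements)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_all_table_symbols_resolve(self):
        for sym in TABLE_SYMBOLS:
            Z, A, I = ELEMENTS[sym]
            assert Z >= 1 and A > 0 and I > 0

    def test_pmma_entry_layer_fractions(self):
        ph = builtin_phantom("biomaterial")
        mat = ph.layers[0].material
        assert mat.name == "PMMA"
        fracs = {e.symbol: e.atomic_fraction for e in mat.elements}
        # 53.3/33.3/13.3 renormalized by their 99.9 sum
        assert fracs["H"] == pytest.approx(53.3 / 99.9, abs=1e-9)
        assert fracs["C"] == pytest.approx(33.3 / 99.9, abs=1e-9)
        assert fracs["O"] == pytest.approx(13.3 / 99.9, abs=1e-9)

    def test_saliva_layer(self):
        ph = builtin_phantom("tissue")
        layer = ph.layers[6]
        assert layer.material.name == "Saliva"
        fracs = {e.symbol: e.atomic_fraction for e in layer.material.elements}
        assert fracs["H"] == pytest.approx(2.0 / 3.0, abs=1e-3)
        assert fracs["O"] == pytest.approx(1.0 / 3.0, abs=1e-3)
        assert layer.material.mass_density == 1.0
        assert layer.material.atomic_density_1e22 == 10.02

    def test_bone_substitute_is_teflon(self):
        ph = builtin_phantom("biomaterial")
        for layer in ph.layers[8:]:
            assert layer.material.name == "Teflon"
            assert layer.material.mass_density == 2.2
            assert layer.material.atomic_density_1e22 == 7.95

    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ValueError, match="tissue.*biomaterial"):
            builtin_phantom("bone")

    def test_total_depth_is_thickness_sum(self):
        ph = builtin_phantom("tissue")
        assert ph.total_depth_mm == pytest.approx(
            sum(l.thickness_mm for l in ph.layers))


class TestMaterial:
    @given(
        st.dictionaries(
            st.sampled_from(TABLE_SYMBOLS),
            st.floats(0.01, 200.0, allow_nan=False),
            min_size=1, max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_fractions_always_renormalized(self, percents):
        mat = Material.from_percents("m", percents, 5.0, 1.0)
        assert sum(e.atomic_fraction for e in mat.elements) == pytest.approx(
            1.0, abs=1e-9)

    def test_unknown_symbol_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            Material.from_percents("m", {"Xx": 100.0}, 5.0, 1.0)

    def test_zero_fractions_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            Material.from_percents("m", {"H": 0.0}, 5.0, 1.0)

    def test_nonpositive_densities_rejected(self):
        with pytest.raises(ValueError):
            Material.from_percents("m", {"H": 100.0}, -1.0, 1.0)
        with pytest.raises(ValueError):
            Material.from_percents("m", {"H": 100.0}, 5.0, 0.0)


class TestNumberDensities:
    def test_water_split(self, water):
        nd = number_densities(water)
        assert nd["H"] == pytest.approx(6.68e22, rel=1e-3)
        assert nd["O"] == pytest.approx(3.34e22, rel=1e-2)
        assert sum(nd.values()) == pytest.approx(water.atomic_density_cm3,
                                                 rel=1e-6)

    def test_single_element_identity(self):
        mat = Material.from_percents("graphite", {"C": 100.0}, 11.3, 2.25)
        assert number_densities(mat)["C"] == pytest.approx(11.3e22)

    def test_pmma_hand_multiplication(self):
        ph = builtin_phantom("biomaterial")
        nd = number_densities(ph.layers[0].material)
        # fractions renormalized by 99.9 then scaled by 8.57e22
        assert nd["H"] == pytest.approx(53.3 / 99.9 * 8.57e22, rel=1e-9)
        assert nd["O"] == pytest.approx(13.3 / 99.9 * 8.57e22, rel=1e-9)


class TestConfigIO:
    WATER_CFG = """
name: single-slab
layers:
  - material: Water
    elements: {H: 2, O: 1}
    atomic_density_1e22: 10.02
    mass_density: 1.0
    thickness_mm: 50.0
"""

    def test_single_layer_water_config(self):
        ph = load_phantom(self.WATER_CFG)
        assert ph.total_depth_mm == pytest.approx(50.0)
        fracs = {e.symbol: e.atomic_fraction
                 for e in ph.layers[0].material.elements}
        assert fracs["H"] == pytest.approx(2.0 / 3.0)

    def test_over_100_percent_renormalized(self):
        cfg = self.WATER_CFG.replace("{H: 2, O: 1}", "{H: 73.7, O: 36.8}")
        ph = load_phantom(cfg)
        assert sum(e.atomic_fraction
                   for e in ph.layers[0].material.elements) == pytest.approx(
            1.0, abs=1e-9)

    def test_empty_layer_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            load_phantom("name: x\nlayers: []\n")

    def test_negative_thickness_rejected(self):
        cfg = self.WATER_CFG.replace("thickness_mm: 50.0", "thickness_mm: -1")
        with pytest.raises(ValueError, match="thickness"):
            load_phantom(cfg)

    def test_unknown_element_rejected_by_name(self):
        cfg = self.WATER_CFG.replace("{H: 2, O: 1}", "{Qq: 1}")
        with pytest.raises(ValueError, match="Qq"):
            load_phantom(cfg)

    @pytest.mark.parametrize("variant", ["tissue", "biomaterial"])
    def test_roundtrip_preserves_numbers(self, variant):
        ph = builtin_phantom(variant)
        buf = io.StringIO()
        save_phantom(ph, buf)
        ph2 = load_phantom(buf.getvalue())
        assert len(ph2.layers) == len(ph.layers)
        for a, b in zip(ph.layers, ph2.layers):
            assert b.thickness_mm == pytest.approx(a.thickness_mm, rel=1e-9)
            assert b.material.atomic_density_1e22 == pytest.approx(
                a.material.atomic_density_1e22, rel=1e-9)
            assert b.material.mass_density == pytest.approx(
                a.material.mass_density, rel=1e-9)
            fa = {e.symbol: e.atomic_fraction for e in a.material.elements}
            fb = {e.symbol: e.atomic_fraction for e in b.material.elements}
            assert fa.keys() == fb.keys()
            for sym in fa:
                assert fb[sym] == pytest.approx(fa[sym], rel=1e-9)

    def test_layer_table_csv(self):
        text = phantom_table(builtin_phantom("tissue"))
        lines = text.strip().splitlines()
        assert lines[0].startswith("index,name,thickness_mm")
        assert len(lines) == 11
        assert "Cortical bone" in text
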