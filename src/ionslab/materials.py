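"""Elements, compound materials, slab layers and phantoms.

A :class:`Phantom` is an ordered stack of homogeneous plane-parallel slabs
(entry surface first), each slab a compound :class:`Material` described by
atomic composition, atomic number density and mass density.  The module
ships the two ten-layer mandible plate phantoms used throughout the
package — one built from real oral tissues, one from tissue-equivalent
polymeric biomaterials (PMMA, parylene N, polyethylene, water, PTFE) — and
reads/writes a small YAML configuration format for user-defined phantoms.

Compositions are atomic percent.  Several published tissue rows do not sum
to exactly 100; fractions are therefore always renormalized to unit sum,
which is the only self-consistent reading because the atomic density of
each compound is specified independently.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ELEMENTS",
    "ElementSpec",
    "Material",
    "Layer",
    "Phantom",
    "builtin_phantom",
    "load_phantom",
    "save_phantom",
    "number_densities",
    "phantom_table",
]

# symbol -> (Z, standard atomic weight [amu], mean excitation energy I [eV])
# I values follow the ICRU-49 elemental recommendations.
ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "F": (9, 18.998, 115.0),
    "Na": (11, 22.990, 149.0),
    "Mg": (12, 24.305, 156.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "K": (19, 39.098, 190.0),
    "Ca": (20, 40.078, 191.0),
    "Fe": (26, 55.845, 286.0),
}

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class ElementSpec:
    """One element of a compound with its normalized atomic fraction."""

    symbol: str
    Z: int
    A: float
    atomic_fraction: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if not 0.0 <= self.atomic_fraction <= 1.0:
            raise ValueError(
                f"atomic_fraction must lie in [0, 1], got {self.atomic_fraction}"
            )


def _element(symbol: str, fraction: float) -> ElementSpec:
    try:
        Z, A, _ = ELEMENTS[symbol]
    except KeyError:
        known = ", ".join(ELEMENTS)
        raise ValueError(
            f"unknown element symbol {symbol!r}; known symbols: {known}"
        ) from None
    return ElementSpec(symbol=symbol, Z=Z, A=A, atomic_fraction=fraction)


@dataclass(frozen=True)
class Material:
    """Homogeneous compound.

    Parameters
    ----------
    name:
        Label, e.g. ``"PMMA"``.
    elements:
        Ordered element specs; fractions are renormalized to unit sum at
        construction.
    atomic_density_1e22:
        Total atomic number density in units of 1e22 atoms/cm^3.
    mass_density:
        Mass density in g/cm^3.
    """

    name: str
    elements: tuple[ElementSpec, ...]
    atomic_density_1e22: float
    mass_density: float

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"material {self.name!r} has no elements")
        if self.atomic_density_1e22 <= 0:
            raise ValueError(f"atomic_density must be > 0 in {self.name!r}")
        if self.mass_density <= 0:
            raise ValueError(f"mass_density must be > 0 in {self.name!r}")
        total = sum(e.atomic_fraction for e in self.elements)
        if total <= 0:
            raise ValueError(f"fractions of {self.name!r} sum to zero")
        if abs(total - 1.0) > _FRACTION_TOL:
            normalized = tuple(
                ElementSpec(e.symbol, e.Z, e.A, e.atomic_fraction / total)
                for e in self.elements
            )
            object.__setattr__(self, "elements", normalized)

    @classmethod
    def from_percents(
        cls,
        name: str,
        percents: dict[str, float],
        atomic_density_1e22: float,
        mass_density: float,
    ) -> "Material":
        """Build from a ``{symbol: percent}`` mapping (any positive scale)."""
        if any(pct < 0 for pct in percents.values()):
            raise ValueError(f"negative fraction in {name!r}")
        total = sum(percents.values())
        if total <= 0:
            raise ValueError(f"fractions of {name!r} sum to zero")
        elems = tuple(_element(sym, pct / total) for sym, pct in percents.items())
        return cls(name, elems, atomic_density_1e22, mass_density)

    @property
    def atomic_density_cm3(self) -> float:
        """Total atomic number density in atoms/cm^3."""
        return self.atomic_density_1e22 * 1e22

    @property
    def electron_density_cm3(self) -> float:
        """Electron number density in electrons/cm^3."""
        mean_Z = sum(e.atomic_fraction * e.Z for e in self.elements)
        return self.atomic_density_cm3 * mean_Z

    @property
    def mean_excitation_energy_eV(self) -> float:
        """Bragg-additivity mean excitation energy: ln I = sum f_i Z_i ln I_i / sum f_i Z_i."""
        import math

        num = 0.0
        den = 0.0
        for e in self.elements:
            I_i = ELEMENTS[e.symbol][2]
            w = e.atomic_fraction * e.Z
            num += w * math.log(I_i)
            den += w
        return math.exp(num / den)

    def composition_str(self) -> str:
        return ", ".join(
            f"{e.symbol}:{100 * e.atomic_fraction:.2f}" for e in self.elements
        )


def number_densities(material: Material) -> dict[str, float]:
    """Per-element number densities in atoms/cm^3.

    The per-element density is ``atomic_density * atomic_fraction``; the
    values sum back to the total atomic density.
    """
    return {
        e.symbol: material.atomic_density_cm3 * e.atomic_fraction
        for e in material.elements
    }


@dataclass(frozen=True)
class Layer:
    material: Material
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError(
                f"layer thickness must be > 0, got {self.thickness_mm} mm "
                f"({self.material.name})"
            )


@dataclass(frozen=True)
class Phantom:
    """Ordered slab stack; ``layers[0]`` is the entry surface."""

    name: str
    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError(f"phantom {self.name!r} has no layers")

    @property
    def total_depth_mm(self) -> float:
        return sum(l.thickness_mm for l in self.layers)

    @property
    def boundaries_mm(self) -> tuple[float, ...]:
        """Cumulative depth of each layer interface, starting at 0."""
        out = [0.0]
        for l in self.layers:
            out.append(out[-1] + l.thickness_mm)
        return tuple(out)

    @property
    def element_symbols(self) -> tuple[str, ...]:
        """Union of element symbols over all layers, in first-seen order."""
        seen: list[str] = []
        for l in self.layers:
            for e in l.material.elements:
                if e.symbol not in seen:
                    seen.append(e.symbol)
        return tuple(seen)

    def material_at(self, depth_mm: float) -> Material:
        if depth_mm < 0 or depth_mm > self.total_depth_mm:
            raise ValueError(f"depth {depth_mm} mm outside phantom")
        acc = 0.0
        for l in self.layers:
            acc += l.thickness_mm
            if depth_mm <= acc:
                return l.material
        return self.layers[-1].material


# ---------------------------------------------------------------------------
# Built-in mandible plate phantom fixtures
# ---------------------------------------------------------------------------
# Published compound table for the ten-layer mandible plate phantom:
# composition in atomic percent (renormalized at load), atomic density in
# 1e22 atoms/cm^3, mass density in g/cm^3.  The tissue rows are stored
# exactly as published even where the percentages are internally
# inconsistent (e.g. the skin row sums to ~110); no correction is guessed.

_TISSUE_ROWS: list[tuple[str, dict[str, float], float, float]] = [
    ("Skin", {"H": 10.0, "O": 59.4, "C": 25.0, "N": 4.6, "S": 0.3, "Cl": 0.3,
              "P": 10.3, "Na": 0.2, "K": 0.1}, 9.88, 1.02),
    ("Parotid gland", {"H": 62.5, "C": 16.4, "N": 1.27, "O": 19.6, "S": 0.037,
                       "Cl": 0.016, "Na": 0.025, "P": 0.019}, 10.32, 1.02),
    ("SMAS", {"H": 58.3, "C": 37.4, "N": 1.45, "O": 1.89, "F": 0.532,
              "Ca": 0.266}, 10.65, 1.027),
    ("Masseter muscle", {"H": 52.6, "C": 8.9, "N": 1.6, "O": 26.6, "S": 5.85,
                         "Cl": 1.76, "K": 0.64, "P": 0.404}, 10.11, 1.05),
    ("Buccal fat", {"H": 63.4, "C": 28.4, "N": 0.304, "O": 7.77, "Cl": 0.018,
                    "Na": 0.011}, 10.35, 0.92),
    ("Mucosa", {"H": 10.1, "C": 77.5, "N": 3.50, "O": 5.23, "F": 1.74,
                "Ca": 1.83}, 5.24, 1.028),
    ("Saliva", {"H": 66.6, "O": 33.3}, 10.02, 1.0),
    ("Gum", {"H": 52.6, "C": 32.9, "N": 0.862, "O": 7.89, "Cl": 1.72,
             "Mg": 3.63}, 8.88, 1.0),
    ("Cortical bone", {"H": 39.2, "C": 15.0, "N": 3.48, "O": 31.6, "S": 0.108,
                       "P": 3.86, "Ca": 6.53, "Mg": 9.57}, 9.94, 1.92),
    ("Cancellous bone", {"H": 57.7, "C": 23.0, "N": 1.36, "O": 15.7, "S": 4.27,
                         "P": 0.752, "Ca": 1.26, "Fe": 1.23}, 10.42, 1.18),
]

_PMMA = ("PMMA", {"H": 53.3, "C": 33.3, "O": 13.3}, 8.57, 0.95)

_BIOMATERIAL_ROWS: list[tuple[str, dict[str, float], float, float]] = [
    _PMMA,                                                     # skin
    _PMMA,                                                     # parotid gland
    _PMMA,                                                     # SMAS
    ("Parylene N", {"H": 50.0, "C": 50.0}, 10.26, 1.11),       # masseter muscle
    ("Polyethylene", {"H": 66.6, "C": 33.4}, 12.23, 0.95),     # buccal fat
    _PMMA,                                                     # mucosa
    ("Water", {"H": 66.6, "O": 33.3}, 10.02, 1.0),             # saliva
    _PMMA,                                                     # gum
    ("Teflon", {"C": 33.3, "F": 66.6}, 7.95, 2.2),             # cortical bone
    ("Teflon", {"C": 33.3, "F": 66.6}, 7.95, 2.2),             # cancellous bone
]

# Default slab thicknesses (mm), entry to exit.  The published study does
# not print thicknesses; these keep anatomically plausible proportions
# (skin : parotid : SMAS : masseter : fat : mucosa : saliva : gum =
# 2 : 8 : 2 : 10 : 5 : 2 : 0.5 : 1.5, cortical + cancellous bone ~ 6 mm)
# scaled so the 354-376 MeV helium Bragg peaks of both material variants
# fall inside the stack (CSDA ranges are 63-71 mm water-equivalent).  All
# thicknesses are overridable through the YAML config.
DEFAULT_THICKNESSES_MM: tuple[float, ...] = (
    4.4, 17.6, 4.4, 22.0, 11.0, 4.4, 1.1, 3.3, 3.0, 4.0
)

_VARIANTS = ("tissue", "biomaterial")


def builtin_phantom(
    variant: str, thicknesses_mm: tuple[float, ...] | None = None
) -> Phantom:
    """Return one of the two shipped ten-layer mandible plate phantoms.

    Parameters
    ----------
    variant:
        ``"tissue"`` (real oral tissues) or ``"biomaterial"`` (polymeric
        tissue substitutes).
    thicknesses_mm:
        Optional per-layer thickness override (10 values, entry first).
    """
    if variant not in _VARIANTS:
        raise ValueError(
            f"unknown phantom variant {variant!r}; valid variants: "
            f"{', '.join(_VARIANTS)}"
        )
    rows = _TISSUE_ROWS if variant == "tissue" else _BIOMATERIAL_ROWS
    th = DEFAULT_THICKNESSES_MM if thicknesses_mm is None else tuple(thicknesses_mm)
    if len(th) != len(rows):
        raise ValueError(f"expected {len(rows)} thicknesses, got {len(th)}")
    layers = tuple(
        Layer(Material.from_percents(name, comp, nd, rho), t)
        for (name, comp, nd, rho), t in zip(rows, th)
    )
    return Phantom(name=f"mandible-{variant}", layers=layers)


# ---------------------------------------------------------------------------
# YAML config I/O
# ---------------------------------------------------------------------------

def _phantom_to_dict(phantom: Phantom) -> dict:
    return {
        "name": phantom.name,
        "layers": [
            {
                "material": l.material.name,
                "elements": {
                    e.symbol: 100.0 * e.atomic_fraction
                    for e in l.material.elements
                },
                "atomic_density_1e22": l.material.atomic_density_1e22,
                "mass_density": l.material.mass_density,
                "thickness_mm": l.thickness_mm,
            }
            for l in phantom.layers
        ],
    }


def save_phantom(phantom: Phantom, dest) -> None:
    """Write a phantom to a YAML file (path or open text handle)."""
    doc = _phantom_to_dict(phantom)
    if hasattr(dest, "write"):
        yaml.safe_dump(doc, dest, sort_keys=False)
    else:
        with open(dest, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_phantom(source) -> Phantom:
    """Load a phantom from YAML (path, open handle, or YAML string).

    The config declares ordered layers with element percents, atomic
    density (1e22 atoms/cm^3), mass density (g/cm^3) and thickness (mm).
    Fractions are renormalized; zero-sum fractions, non-positive
    thickness/density and unknown element symbols are rejected.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    elif isinstance(source, str) and "\n" in source:
        doc = yaml.safe_load(io.StringIO(source))
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "layers" not in doc:
        raise ValueError("phantom config must be a mapping with a 'layers' list")
    layer_docs = doc["layers"]
    if not layer_docs:
        raise ValueError("phantom config has an empty layer list")
    layers = []
    for i, ld in enumerate(layer_docs):
        try:
            mat = Material.from_percents(
                str(ld.get("material", f"layer{i + 1}")),
                {str(k): float(v) for k, v in ld["elements"].items()},
                float(ld["atomic_density_1e22"]),
                float(ld["mass_density"]),
            )
            layers.append(Layer(mat, float(ld["thickness_mm"])))
        except KeyError as exc:
            raise ValueError(f"layer {i + 1} is missing key {exc}") from None
    return Phantom(name=str(doc.get("name", "phantom")), layers=tuple(layers))


def phantom_table(phantom: Phantom, dest=None) -> str:
    """CSV export of the layer table; returns the CSV text."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(
        ["index", "name", "thickness_mm", "mass_density",
         "atomic_density_1e22", "composition"]
    )
    for i, l in enumerate(phantom.layers, start=1):
        writer.writerow(
            [i, l.material.name, f"{l.thickness_mm:g}",
             f"{l.material.mass_density:g}",
             f"{l.material.atomic_density_1e22:g}",
             l.material.composition_str()]
        )
    text = buf.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text
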