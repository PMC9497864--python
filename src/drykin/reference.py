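"""Published reference values for convective drying of plantain banana slices.

The study dried green plantain banana slices (2, 4, 6, 8 mm) in a laboratory
tray dryer at 50-80 degC and 1.5 m/s air velocity, and reported per-condition
diffusion-approach model parameters, effective moisture diffusivities, mass
transfer properties, per-thickness activation energies and slice hardness.
These constants serve two purposes: they are the default generating
parameters of :mod:`drykin.synthetic` (the synthetic study emulates the
reported conditions) and the inputs/benchmarks of the transport-chain
verification utilities.

Moisture contents are stored as fractions (kg water / kg dry matter);
percent dry basis appears only at I/O boundaries.
"""

from __future__ import annotations

AIR_VELOCITY = 1.5
"""Drying air velocity, m/s (constant across the study)."""

INITIAL_LOAD_KG = 0.88
"""Fresh slice load per tray, kg."""

INITIAL_MOISTURE_DB = 5.9812
"""Initial moisture content, kg water / kg dry matter (598.12% d.b.)."""

FINAL_MOISTURE_DB = 0.12
"""Approximate final moisture content, kg/kg d.b. (11.89-12.33% d.b.)."""

TEMPERATURES_C = (50.0, 60.0, 70.0, 80.0)
THICKNESSES_MM = (2.0, 4.0, 6.0, 8.0)

#: Diffusion-approach parameter triples (a, k [1/min], b) per
#: (temperature degC, thickness mm) condition, as reported by the study.
#: Note the 50 degC / 2 mm k is printed to two decimals only.
DIFFUSION_APPROACH_PARAMS: dict[tuple[float, float], tuple[float, float, float]] = {
    (50.0, 2.0): (0.88, 0.03, 0.01),
    (50.0, 4.0): (0.86, 0.0287, 0.0163),
    (50.0, 6.0): (0.85, 0.0249, 0.0174),
    (50.0, 8.0): (0.83, 0.0226, 0.0186),
    (60.0, 2.0): (0.88, 0.0347, 0.0142),
    (60.0, 4.0): (0.86, 0.0304, 0.0177),
    (60.0, 6.0): (0.85, 0.0269, 0.0182),
    (60.0, 8.0): (0.84, 0.0238, 0.0177),
    (70.0, 2.0): (0.87, 0.0402, 0.0329),
    (70.0, 4.0): (0.84, 0.0351, 0.0411),
    (70.0, 6.0): (0.84, 0.0302, 0.0343),
    (70.0, 8.0): (0.83, 0.0278, 0.0284),
    (80.0, 2.0): (0.88, 0.0465, 0.0292),
    (80.0, 4.0): (0.86, 0.0427, 0.0323),
    (80.0, 6.0): (0.85, 0.0386, 0.0291),
    (80.0, 8.0): (0.86, 0.0341, 0.0233),
}

#: Reported transport and texture results per (thickness mm, temperature degC),
#: in the study's row order: deff (m^2/s), Bi (2 d.p.), hm (m/s, 3 s.f.),
#: hardness (N). Activation energies are per thickness group.
TRANSPORT_TABLE: list[dict] = [
    {"row": 1, "thickness_mm": 2.0, "temperature_C": 50.0, "deff": 1.11e-10, "bi": 0.57, "hm": 3.17e-8, "hardness_N": 15.25},
    {"row": 2, "thickness_mm": 2.0, "temperature_C": 60.0, "deff": 1.25e-10, "bi": 0.59, "hm": 3.68e-8, "hardness_N": 17.54},
    {"row": 3, "thickness_mm": 2.0, "temperature_C": 70.0, "deff": 1.41e-10, "bi": 0.62, "hm": 4.38e-8, "hardness_N": 23.75},
    {"row": 4, "thickness_mm": 2.0, "temperature_C": 80.0, "deff": 1.70e-10, "bi": 0.66, "hm": 5.58e-8, "hardness_N": 31.84},
    {"row": 5, "thickness_mm": 4.0, "temperature_C": 50.0, "deff": 3.66e-10, "bi": 0.71, "hm": 6.50e-8, "hardness_N": 26.56},
    {"row": 6, "thickness_mm": 4.0, "temperature_C": 60.0, "deff": 4.00e-10, "bi": 0.73, "hm": 7.26e-8, "hardness_N": 35.70},
    {"row": 7, "thickness_mm": 4.0, "temperature_C": 70.0, "deff": 4.47e-10, "bi": 0.77, "hm": 8.57e-8, "hardness_N": 37.02},
    {"row": 8, "thickness_mm": 4.0, "temperature_C": 80.0, "deff": 5.90e-10, "bi": 0.82, "hm": 1.22e-7, "hardness_N": 38.67},
    {"row": 9, "thickness_mm": 6.0, "temperature_C": 50.0, "deff": 6.89e-10, "bi": 0.78, "hm": 9.01e-8, "hardness_N": 38.23},
    {"row": 10, "thickness_mm": 6.0, "temperature_C": 60.0, "deff": 7.60e-10, "bi": 0.81, "hm": 1.02e-7, "hardness_N": 39.95},
    {"row": 11, "thickness_mm": 6.0, "temperature_C": 70.0, "deff": 8.35e-10, "bi": 0.84, "hm": 1.17e-7, "hardness_N": 45.76},
    {"row": 12, "thickness_mm": 6.0, "temperature_C": 80.0, "deff": 1.14e-9, "bi": 0.92, "hm": 1.76e-7, "hardness_N": 66.13},
    {"row": 13, "thickness_mm": 8.0, "temperature_C": 50.0, "deff": 1.04e-9, "bi": 0.84, "hm": 1.10e-7, "hardness_N": 39.8},
    {"row": 14, "thickness_mm": 8.0, "temperature_C": 60.0, "deff": 1.15e-9, "bi": 0.86, "hm": 1.24e-7, "hardness_N": 41.65},
    {"row": 15, "thickness_mm": 8.0, "temperature_C": 70.0, "deff": 1.28e-9, "bi": 0.91, "hm": 1.46e-7, "hardness_N": 50.36},
    {"row": 16, "thickness_mm": 8.0, "temperature_C": 80.0, "deff": 1.79e-9, "bi": 0.98, "hm": 2.20e-7, "hardness_N": 71.41},
]

#: Reported activation energy per slice thickness, kJ/mol.
ACTIVATION_ENERGY_KJ_MOL: dict[float, float] = {
    2.0: 13.70,
    4.0: 15.82,
    6.0: 16.93,
    8.0: 18.23,
}

#: Reported four-group sample partition from the dendrogram analysis,
#: keyed by the 1-based row numbers of the transport table.
REPORTED_CLUSTERS: list[set[int]] = [
    {1, 2, 5, 6},
    {3, 4, 7, 8},
    {9, 10, 11, 12, 16},
    {13, 14, 15},
]


def reference_deff(thickness_mm: float, temperature_C: float) -> float:
    """Reported effective moisture diffusivity (m^2/s) for one condition."""
    for row in TRANSPORT_TABLE:
        if row["thickness_mm"] == thickness_mm and row["temperature_C"] == temperature_C:
            return row["deff"]
    raise KeyError(f"no reference condition {thickness_mm} mm / {temperature_C} degC")
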