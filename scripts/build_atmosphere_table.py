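"""Regenerate the packaged US Standard Atmosphere 1976 table.

Writes ``src/aeroloft/data/ussa1976.csv`` with columns
``z_m, rho_kg_m3, T_K, mfp_m`` on a geometric-altitude grid: 2 km steps from
the surface to 70 km, then 1 km steps up to 200 km so that the altitudes the
worked examples cite (90 km, 100 km) are exact nodes.

Below 86 km the table is the analytic seven-layer USSA 1976 barometric
profile. From 86 km upward, where the standard atmosphere is defined by a
numerically integrated composition model rather than a closed form, tabulated
USSA 1976 anchor values (density, kinetic temperature, mean molecular weight)
are densified to 1 km with the same log-linear density rule the profile
interpolator uses, so interpolation and tabulation agree by construction.

The mean free path column follows the USSA 1976 definition
``lambda = 1 / (sqrt(2) pi sigma^2 n)`` with effective collision diameter
``sigma = 3.65e-10 m`` and number density ``n = rho * N_A / M``.
"""
from __future__ import annotations

import math
import pathlib

G0 = 9.80665          # m s-2
R_STAR = 8.31432e3    # J kmol-1 K-1
M0 = 28.9644          # kg kmol-1, sea-level mean molecular weight
R_EARTH_GP = 6356.766e3  # m, radius used for geopotential conversion
SIGMA = 3.65e-10      # m, effective collision diameter
N_A = 6.022169e26     # kmol-1

# (H_b geopotential km, T_b K, L_b K/km, P_b Pa)
LAYERS = [
    (0.0, 288.15, -6.5, 101325.0),
    (11.0, 216.65, 0.0, 22632.06),
    (20.0, 216.65, 1.0, 5474.889),
    (32.0, 228.65, 2.8, 868.0187),
    (47.0, 270.65, 0.0, 110.9063),
    (51.0, 270.65, -2.8, 66.93887),
    (71.0, 214.65, -2.0, 3.956420),
]

# USSA 1976 upper-atmosphere anchors: z km, T K, rho kg m-3, M kg kmol-1
UPPER_ANCHORS = [
    (86, 186.87, 6.958e-06, 28.95),
    (90, 186.87, 3.416e-06, 28.91),
    (95, 188.42, 1.393e-06, 28.73),
    (100, 195.08, 5.604e-07, 28.40),
    (105, 208.84, 2.325e-07, 27.88),
    (110, 240.00, 9.708e-08, 27.27),
    (115, 300.00, 4.289e-08, 26.68),
    (120, 360.00, 2.222e-08, 26.20),
    (130, 469.27, 8.152e-09, 25.44),
    (140, 559.63, 3.831e-09, 24.75),
    (150, 634.39, 2.076e-09, 24.10),
    (160, 696.29, 1.233e-09, 23.49),
    (170, 747.57, 7.815e-10, 22.93),
    (180, 790.07, 5.194e-10, 22.34),
    (190, 825.31, 3.581e-10, 21.81),
    (200, 854.56, 2.541e-10, 21.30),
]


def lower_atmosphere(z_m: float) -> tuple[float, float, float]:
    """Analytic USSA 1976 below 86 km: (rho, T, M) at geometric altitude."""
    h_km = (R_EARTH_GP * z_m / (R_EARTH_GP + z_m)) / 1000.0
    base = LAYERS[0]
    for layer in LAYERS:
        if h_km >= layer[0]:
            base = layer
    h_b, t_b, lapse, p_b = base
    t = t_b + lapse * (h_km - h_b)
    if lapse == 0.0:
        p = p_b * math.exp(-G0 * M0 * (h_km - h_b) * 1000.0 / (R_STAR * t_b))
    else:
        p = p_b * (t_b / t) ** (G0 * M0 / (R_STAR * lapse / 1000.0))
    rho = p * M0 / (R_STAR * t)
    return rho, t, M0


def mean_free_path(rho: float, mol_weight: float) -> float:
    n = rho * N_A / mol_weight
    return 1.0 / (math.sqrt(2.0) * math.pi * SIGMA**2 * n)


def upper_atmosphere(z_km: float) -> tuple[float, float, float]:
    """Anchor interpolation above 86 km: log-linear rho, linear T and M."""
    for (z0, t0, rho0, m0), (z1, t1, rho1, m1) in zip(
        UPPER_ANCHORS, UPPER_ANCHORS[1:]
    ):
        if z0 <= z_km <= z1:
            f = (z_km - z0) / (z1 - z0)
            rho = rho0 * (rho1 / rho0) ** f
            return rho, t0 + f * (t1 - t0), m0 + f * (m1 - m0)
    raise ValueError(f"altitude {z_km} km outside anchor span")


def build_rows() -> list[tuple[float, float, float, float]]:
    rows = []
    grid_km = [float(z) for z in range(0, 70, 2)] + [
        float(z) for z in range(70, 201)
    ]
    for z_km in grid_km:
        if z_km < 86.0:
            rho, t, m = lower_atmosphere(z_km * 1000.0)
        else:
            rho, t, m = upper_atmosphere(z_km)
        rows.append((z_km * 1000.0, rho, t, mean_free_path(rho, m)))
    return rows


def main() -> None:
    out = (
        pathlib.Path(__file__).resolve().parents[1]
        / "src"
        / "aeroloft"
        / "data"
        / "ussa1976.csv"
    )
    with out.open("w") as fh:
        fh.write("z_m,rho_kg_m3,T_K,mfp_m\n")
        for z, rho, t, mfp in build_rows():
            fh.write(f"{z:.0f},{rho:.6e},{t:.2f},{mfp:.6e}\n")
    print(f"wrote {out} ({len(build_rows())} rows)")


if __name__ == "__main__":
    main()
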