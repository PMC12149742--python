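"""Liquid junction potential by the Henderson (stationary Nernst-Planck)
approximation.

For a free-diffusion junction between two solutions A (pipette) and B
(bath), with ion charges z_i, limiting equivalent conductivities lambda_i
(proportional to mobility) and concentrations c_i, the Henderson equation
gives the potential of the bath relative to the pipette:

    E = (RT/F) * [ S1 / S2 ] * ln( S3_A / S3_B )

    S1 = sum_i sgn(z_i) * lambda_i * (c_i^B - c_i^A)
    S2 = sum_i |z_i| * lambda_i * (c_i^B - c_i^A)
    S3_X = sum_i |z_i| * lambda_i * c_i^X

With this sign convention a potassium-gluconate pipette against a NaCl bath
gives a positive potential of 10-17 mV (the slow gluconate anion leaves the
pipette side negative), matching how junction potentials are reported for
whole-cell recording.

Compound solutions are speciated with fixed rules (see
``DISSOCIATION``): salts dissociate fully, Mg-ATP contributes Mg2+ and
ATP2-, Na-GTP contributes 2 Na+ and GTP2-, EGTA is divalent-anionic at
pH ~7.2, HEPES is 50% anionic (pK_a 7.5 near pH 7.2-7.4) with the titrated
fraction balanced by the hydroxide counterion (KOH or NaOH), and sugars are
neutral and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IonSpecies",
    "Solution",
    "henderson_ljp",
    "stationary_np_ljp",
    "solution_from_compounds",
    "MOBILITY_TABLE",
    "DISSOCIATION",
]

#: limiting equivalent ionic conductivities at 25 C (S cm^2/equiv) and
#: charge.  Small organic anions (gluconate, HEPES, nucleotides, EGTA) from
#: the values used by the standard junction-potential calculators.
MOBILITY_TABLE: dict[str, tuple[int, float]] = {
    "Na": (+1, 50.11),
    "K": (+1, 73.50),
    "Cs": (+1, 77.30),
    "Li": (+1, 38.70),
    "Mg": (+2, 53.06),
    "Ca": (+2, 59.50),
    "Cl": (-1, 76.35),
    "F": (-1, 55.40),
    "gluconate": (-1, 24.30),
    "HEPES": (-1, 22.05),
    "MES": (-1, 26.80),
    "EGTA": (-2, 24.00),
    "ATP": (-2, 25.00),
    "GTP": (-2, 25.00),
    "OH": (-1, 198.00),
}

#: compound -> list of (species, stoichiometry).  Fractional stoichiometry
#: expresses partial protonation (HEPES ~50% anionic at pH 7.2-7.4).
DISSOCIATION: dict[str, list[tuple[str, float]]] = {
    "NaCl": [("Na", 1), ("Cl", 1)],
    "KCl": [("K", 1), ("Cl", 1)],
    "CsCl": [("Cs", 1), ("Cl", 1)],
    "MgCl2": [("Mg", 1), ("Cl", 2)],
    "CaCl2": [("Ca", 1), ("Cl", 2)],
    "K-gluconate": [("K", 1), ("gluconate", 1)],
    "Na-gluconate": [("Na", 1), ("gluconate", 1)],
    "HEPES": [("HEPES", 0.5)],
    "EGTA": [("EGTA", 1)],
    "Mg-ATP": [("Mg", 1), ("ATP", 1)],
    "Na-GTP": [("Na", 2), ("GTP", 1)],
    "Na2-ATP": [("Na", 2), ("ATP", 1)],
    "glucose": [],
    "sucrose": [],
}

#: titrant cation per hydroxide base used to adjust pH
_TITRANT_CATION = {"KOH": "K", "NaOH": "Na", "CsOH": "Cs"}


@dataclass(frozen=True)
class IonSpecies:
    name: str
    charge: int
    concentration_mm: float
    mobility: float  # limiting equivalent conductivity, S cm^2/equiv

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("contributing species must be charged")
        if self.concentration_mm < 0:
            raise ValueError("concentration must be non-negative")
        if self.mobility <= 0:
            raise ValueError("mobility must be positive")


@dataclass
class Solution:
    species: list[IonSpecies]
    temperature_k: float = 298.15
    name: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("solution has no charged species")
        cat = sum(s.charge * s.concentration_mm for s in self.species if s.charge > 0)
        an = -sum(s.charge * s.concentration_mm for s in self.species if s.charge < 0)
        if cat > 0 and an > 0:
            imbalance = abs(cat - an) / max(cat, an)
            if imbalance > 0.05:
                raise ValueError(
                    f"solution {self.name or '<unnamed>'} charge-imbalanced by "
                    f"{imbalance:.1%} (cations {cat:.1f}, anions {an:.1f} meq)"
                )


def solution_from_compounds(
    compounds_mm: dict[str, float],
    titrant: str | None = None,
    temperature_k: float = 298.15,
    name: str = "",
) -> Solution:
    """Build a Solution from compound concentrations (mM).

    ``titrant`` ('KOH' or 'NaOH') adds the hydroxide counter-cation needed
    to balance any net negative charge from partially/fully anionic buffers
    (pH adjustment); the hydroxide itself is consumed by protonation and
    contributes no mobile OH-.
    """
    totals: dict[str, float] = {}
    for compound, conc in compounds_mm.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {compound}")
        if compound not in DISSOCIATION:
            raise ValueError(
                f"no dissociation rule for compound {compound!r}; known: "
                f"{sorted(DISSOCIATION)}"
            )
        for species, stoich in DISSOCIATION[compound]:
            totals[species] = totals.get(species, 0.0) + stoich * conc

    if titrant is not None:
        if titrant not in _TITRANT_CATION:
            raise ValueError(f"unknown titrant {titrant!r}")
        cat = sum(
            MOBILITY_TABLE[s][0] * c for s, c in totals.items() if MOBILITY_TABLE[s][0] > 0
        )
        an = -sum(
            MOBILITY_TABLE[s][0] * c for s, c in totals.items() if MOBILITY_TABLE[s][0] < 0
        )
        if an > cat:
            sp = _TITRANT_CATION[titrant]
            totals[sp] = totals.get(sp, 0.0) + (an - cat)

    species = []
    for sp, conc in sorted(totals.items()):
        if conc <= 0:
            continue
        if sp not in MOBILITY_TABLE:
            raise ValueError(f"species {sp!r} missing from the mobility table")
        z, lam = MOBILITY_TABLE[sp]
        species.append(IonSpecies(sp, z, conc, lam))
    return Solution(species, temperature_k=temperature_k, name=name)


def henderson_ljp(pipette: Solution, bath: Solution) -> float:
    """Henderson junction potential (mV) of the bath relative to the
    pipette solution."""
    if abs(pipette.temperature_k - bath.temperature_k) > 1e-6:
        raise ValueError("solutions must share a temperature")
    t = pipette.temperature_k
    rt_over_f_mv = 1000.0 * 8.314462618 * t / 96485.33212

    def accumulate(sol: Solution) -> dict[str, tuple[int, float, float]]:
        out: dict[str, tuple[int, float, float]] = {}
        for s in sol.species:
            if s.name in out:
                z, lam, c = out[s.name]
                out[s.name] = (z, lam, c + s.concentration_mm)
            else:
                out[s.name] = (s.charge, s.mobility, s.concentration_mm)
        return out

    a = accumulate(pipette)
    b = accumulate(bath)
    names = sorted(set(a) | set(b))

    s1 = s2 = s3a = s3b = 0.0
    for nm in names:
        z, lam, ca = a.get(nm, (None, None, 0.0))
        zb, lamb, cb = b.get(nm, (z, lam, 0.0))
        if z is None:
            z, lam = zb, lamb
        s1 += np.sign(z) * lam * (cb - ca)
        s2 += abs(z) * lam * (cb - ca)
        s3a += abs(z) * lam * ca
        s3b += abs(z) * lam * cb

    if s3a <= 0 or s3b <= 0:
        raise ValueError("both solutions need charged species")
    if abs(s2) < 1e-12:
        # identical conductivity-weighted content: no junction potential
        return 0.0
    return float(rt_over_f_mv * (s1 / s2) * np.log(s3a / s3b))


def _species_arrays(pipette: Solution, bath: Solution):
    def totals(sol: Solution) -> dict[str, float]:
        out: dict[str, float] = {}
        for s in sol.species:
            out[s.name] = out.get(s.name, 0.0) + s.concentration_mm
        return out

    info: dict[str, tuple[int, float]] = {}
    for s in pipette.species + bath.species:
        info.setdefault(s.name, (s.charge, s.mobility))
    ca_d, cb_d = totals(pipette), totals(bath)
    names = sorted(info)
    z = np.array([info[n][0] for n in names], dtype=float)
    lam = np.array([info[n][1] for n in names], dtype=float)
    ca = np.array([ca_d.get(n, 0.0) for n in names])
    cb = np.array([cb_d.get(n, 0.0) for n in names])
    return names, z, lam, ca, cb


def stationary_np_ljp(pipette: Solution, bath: Solution) -> float:
    """Junction potential (mV, bath relative to pipette) from a numerical
    solution of the stationary Nernst-Planck system.

    Constant ion fluxes across the junction, local electroneutrality, and
    zero net current; the boundary-value problem is solved by shooting on
    the fluxes.  This is the model implemented by the common LJP calculator
    software; it relaxes the Henderson assumption of linearly mixed
    concentration profiles and typically differs from the closed form by a
    fraction of a millivolt for physiological solutions.
    """
    from scipy.integrate import solve_ivp
    from scipy.optimize import root

    if abs(pipette.temperature_k - bath.temperature_k) > 1e-6:
        raise ValueError("solutions must share a temperature")
    rt_over_f_mv = 1000.0 * 8.314462618 * pipette.temperature_k / 96485.33212

    _, z, lam, ca, cb = _species_arrays(pipette, bath)
    d = lam / np.abs(z)  # relative diffusion coefficients
    n = z.size
    if n < 2:
        raise ValueError("need at least two ion species")
    if np.allclose(ca, cb):
        return 0.0

    def rhs(x, y, flux):
        c = np.maximum(y[:n], 1e-12)
        phi_p = -(z @ (flux / d)) / (z * z @ c)  # field in RT/F units
        dc = -flux / d - z * c * phi_p
        return np.concatenate([dc, [phi_p]])

    def shoot(flux):
        y0 = np.concatenate([ca, [0.0]])
        sol = solve_ivp(rhs, (0.0, 1.0), y0, args=(flux,), method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError("stationary Nernst-Planck integration failed")
        return sol.y[:, -1]

    def residual(flux):
        yf = shoot(flux)
        return np.append((yf[:n] - cb)[:-1], z @ flux)

    guess = d * (ca - cb)
    sol = root(residual, guess, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6 * max(1.0, cb.max()):
        raise RuntimeError(
            "stationary Nernst-Planck boundary-value solve did not converge"
        )
    return float(shoot(sol.x)[n] * rt_over_f_mv)
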