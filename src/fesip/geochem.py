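"""Per-microcosm electron and ¹³C mass balances.

The experimental system is a sealed anoxic soil-slurry microcosm fed
¹³C-acetate, with ferrihydrite (FER), goethite (GOE) or no Fe(III)
oxyhydroxide (CTR) as terminal electron acceptor.  This module holds the
arithmetic behind the two summary tables such a study reports:

* an *electron balance* — complete oxidation of acetate
  (CH₃COO⁻ + 2 H₂O → 2 CO₂ + 8 e⁻ + 7 H⁺) yields 8 electron equivalents per
  mole, and each Fe(III)→Fe(II) transition consumes exactly one, so the share
  of acetate-derived electrons flowing into iron reduction is
  100 · ΔFe(II) / (8 · Δacetate);
* a *¹³C recovery* — the fraction of added ¹³C re-found as headspace ¹³CH₄,
  headspace ¹³CO₂ and dissolved inorganic ¹³C (carbonic acid + bicarbonate +
  carbonate, partitioned from the headspace via Henry's law and the two
  carbonic-acid dissociation constants at the measured slurry pH).

Quantities are reported table-style: electron percentages at two significant
figures, recoveries at integer percent, both rounded half-away-from-zero.
"""

from __future__ import annotations

import decimal
import math
import warnings
from dataclasses import dataclass

from fesip.errors import (
    ConfigError,
    MeasurementInconsistencyError,
    UndefinedRatioError,
)

#: Electron equivalents released by complete oxidation of one acetate.
ELECTRONS_PER_ACETATE = 8
#: One electron reduces one Fe(III) to Fe(II).
ELECTRONS_PER_FE = 1
#: Fe atoms per ferrihydrite formula unit, Fe₅HO₈·4H₂O.
FE_PER_FERRIHYDRITE_UNIT = 5
#: Ideal-gas constant, L atm mol⁻¹ K⁻¹.
R_L_ATM = 0.082057

SOILS = ("NF", "N")
AMENDMENTS = ("FER", "GOE", "CTR")
ISOTOPES = ("C13", "C12")


# ---------------------------------------------------------------------------
# rounding policy
# ---------------------------------------------------------------------------

def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (table convention, not banker's).

    Decimal arithmetic on the shortest decimal representation, so values that
    are exact in decimal (0.145) round by policy, not by binary accident.
    """
    if not math.isfinite(x):
        return x
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, ties away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_away(x, ndigits=sig - 1 - exponent)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrocosmSpec:
    """Identity and physical constants of one incubation vial.

    Defaults follow the incubation design: 5 ml slurry in a 25-ml serum vial
    (20 ml headspace), Fe(III) oxyhydroxide at 140 μmol Fe g⁻¹ dry soil for
    amended vials, 25 °C.  ``soil_dry_mass_g`` converts between per-gram and
    per-vial bookkeeping; it is not directly measured and defaults to 3.0 g,
    the value implied by the ratio of per-vial to per-gram Fe(II) increments.
    """

    soil: str
    amendment: str
    isotope: str = "C13"
    slurry_volume_ml: float = 5.0
    headspace_volume_ml: float = 20.0
    soil_dry_mass_g: float = 3.0
    fe_added_umol_per_g: float = 0.0
    temperature_k: float = 298.15

    def __post_init__(self):
        if self.soil not in SOILS:
            raise ConfigError(f"soil must be one of {SOILS}, got {self.soil!r}")
        if self.amendment not in AMENDMENTS:
            raise ConfigError(
                f"amendment must be one of {AMENDMENTS}, got {self.amendment!r}"
            )
        if self.isotope not in ISOTOPES:
            raise ConfigError(
                f"isotope must be one of {ISOTOPES}, got {self.isotope!r}"
            )
        if self.slurry_volume_ml <= 0 or self.headspace_volume_ml <= 0:
            raise ConfigError("vial volumes must be positive")
        if self.soil_dry_mass_g <= 0:
            raise ConfigError("soil dry mass must be positive")
        if (self.amendment == "CTR") != (self.fe_added_umol_per_g == 0):
            raise ConfigError(
                "fe_added_umol_per_g must be 0 exactly for CTR and nonzero "
                f"for FER/GOE (amendment={self.amendment}, "
                f"fe_added={self.fe_added_umol_per_g})"
            )

    @property
    def microcosm_id(self) -> str:
        return f"{self.soil}-{self.amendment}-{self.isotope}"


@dataclass
class BiogeochemSeries:
    """Time-stamped geochemical and headspace-gas measurements for one vial.

    Solid/solution analytes (``fe2``, ``total_fe``, ``acetate``) are per gram
    dry soil (μmol g⁻¹); gases are per vial (μmol); ¹³C atom percentages are
    0–100; pH dimensionless.
    """

    time_days: list[float]
    fe2: list[float]
    total_fe: list[float]
    acetate: list[float]
    ch4_total: list[float]
    co2_total: list[float]
    atom13_ch4: list[float]
    atom13_co2: list[float]
    ph: list[float]

    def __post_init__(self):
        n = len(self.time_days)
        for name in ("fe2", "total_fe", "acetate", "ch4_total", "co2_total",
                     "atom13_ch4", "atom13_co2", "ph"):
            if len(getattr(self, name)) != n:
                raise MeasurementInconsistencyError(
                    f"series {name!r} length differs from time axis"
                )
        if any(b <= a for a, b in zip(self.time_days, self.time_days[1:])):
            raise MeasurementInconsistencyError("time points must strictly increase")
        for t, a_ch4, a_co2 in zip(self.time_days, self.atom13_ch4, self.atom13_co2):
            for v in (a_ch4, a_co2):
                if not 0.0 <= v <= 100.0:
                    raise MeasurementInconsistencyError(
                        f"atom%13C outside [0, 100] at day {t}: {v}"
                    )
        for t, fe2, tot in zip(self.time_days, self.fe2, self.total_fe):
            if fe2 > tot:
                raise MeasurementInconsistencyError(
                    f"Fe(II) exceeds total extractable Fe at day {t}: "
                    f"{fe2} > {tot}"
                )

    def fe2_formed_umol_per_g(self) -> float:
        """Net Fe(II) increment over the incubation, μmol g⁻¹."""
        return self.fe2[-1] - self.fe2[0]

    def acetate_consumed_umol_per_g(self, added_umol_per_g: float = 0.0) -> float:
        """Net acetate drawdown, μmol g⁻¹, counting replenished pulses.

        ``added_umol_per_g`` is the total substrate added *after* time zero
        (the initial pulse is part of ``acetate[0]``).
        """
        return self.acetate[0] + added_umol_per_g - self.acetate[-1]


@dataclass(frozen=True)
class ElectronBalance:
    """Acetate-derived electron production and its partition to Fe(III)."""

    fe2_formed: float          # μmol
    e_production: float        # meq e⁻ (μmol-scale equivalents)
    e_to_fe: float             # meq e⁻
    percent_to_fe: float       # %, 2 significant figures
    percent_to_fe_raw: float   # unrounded
    acetate_consumed: float | None = None  # μmol, if known
    exceeds_production: bool = False


@dataclass(frozen=True)
class CarbonateSystem:
    """Henry/dissociation constants and phase volumes for CO₂ speciation.

    Defaults are 25 °C freshwater values: K_H = 0.0339 mol L⁻¹ atm⁻¹,
    pK₁ = 6.35, pK₂ = 10.33.  The effective liquid volume defaults to the
    slurry pore-water volume (≈ 5 ml) and the gas volume to the 20-ml
    headspace; all are overridable in configuration.
    """

    kh: float = 0.0339          # mol L⁻¹ atm⁻¹
    pk1: float = 6.35
    pk2: float = 10.33
    temperature_k: float = 298.15
    v_liquid_l: float = 0.005
    v_gas_l: float = 0.020

    def __post_init__(self):
        if self.kh <= 0 or self.temperature_k <= 0:
            raise ConfigError("carbonate constants must be positive")
        if not self.pk1 < self.pk2:
            raise ConfigError("pK1 must be below pK2")
        if self.v_liquid_l <= 0 or self.v_gas_l <= 0:
            raise ConfigError("phase volumes must be positive")


@dataclass(frozen=True)
class CarbonRecovery:
    """¹³C budget: label re-found in gas and solution vs label added."""

    c13_added: float        # μmol
    gas_13ch4: float        # μmol
    gas_13co2: float        # μmol
    dissolved_13co2: float  # μmol
    recovery: float         # %, integer-rounded
    recovery_raw: float     # unrounded

    def __post_init__(self):
        for name in ("c13_added", "gas_13ch4", "gas_13co2", "dissolved_13co2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def acetate_electron_yield(acetate_umol: float) -> float:
    """Electron equivalents (meq e⁻) from complete oxidation of acetate.

    Each mole of acetate fully oxidized to CO₂ releases 8 electron
    equivalents; the theoretical stoichiometry is exact, so the map is
    simply 8 × acetate.
    """
    if acetate_umol < 0:
        raise ValueError(f"acetate consumption cannot be negative: {acetate_umol}")
    return ELECTRONS_PER_ACETATE * acetate_umol


def electron_balance(
    fe2_formed: float,
    e_production: float,
    acetate_consumed: float | None = None,
) -> ElectronBalance:
    """Partition acetate-derived electrons into Fe(III) reduction.

    One electron reduces one Fe(III), so electrons flowed into iron equal the
    Fe(II) formed (in μmol).  The percentage to iron is reported at two
    significant figures.  A partition above 100% is reported as-is with
    ``exceeds_production=True`` (electron donors other than acetate implied),
    never clamped.
    """
    if fe2_formed < 0:
        raise ValueError(f"fe2_formed cannot be negative: {fe2_formed}")
    if e_production <= 0:
        raise UndefinedRatioError(
            "percent-to-Fe is undefined at zero electron production"
        )
    e_to_fe = ELECTRONS_PER_FE * fe2_formed
    raw = 100.0 * e_to_fe / e_production
    exceeds = raw > 100.0
    if exceeds:
        warnings.warn(
            f"electron partition to Fe(III) exceeds production ({raw:.1f}%): "
            "an electron source other than acetate is implied",
            stacklevel=2,
        )
    return ElectronBalance(
        fe2_formed=fe2_formed,
        e_production=e_production,
        e_to_fe=e_to_fe,
        percent_to_fe=round_sig(raw, 2),
        percent_to_fe_raw=raw,
        acetate_consumed=acetate_consumed,
        exceeds_production=exceeds,
    )


def reducible_fe3(total_fe: float, fe2: float, time_day: float | None = None) -> float:
    """Hydroxylamine-reducible Fe(III) as total extractable Fe minus Fe(II)."""
    if fe2 < 0:
        raise ValueError(f"Fe(II) cannot be negative: {fe2}")
    if fe2 > total_fe:
        at = "" if time_day is None else f" at day {time_day}"
        raise MeasurementInconsistencyError(
            f"Fe(II) ({fe2}) exceeds total extractable Fe ({total_fe}){at}"
        )
    return total_fe - fe2


def ferrihydrite_formula_units(fe_umol: float) -> float:
    """μmol of Fe₅HO₈·4H₂O formula units containing ``fe_umol`` of Fe."""
    if fe_umol < 0:
        raise ValueError(f"Fe amount cannot be negative: {fe_umol}")
    return fe_umol / FE_PER_FERRIHYDRITE_UNIT


def labeled_gas_amount(total_gas: float, atom13: float) -> float:
    """μmol of ¹³C-gas in a pool of ``total_gas`` μmol at ``atom13`` atom %."""
    if not 0.0 <= atom13 <= 100.0:
        raise ValueError(f"atom%13C outside [0, 100]: {atom13}")
    if total_gas < 0:
        raise ValueError(f"gas amount cannot be negative: {total_gas}")
    return total_gas * atom13 / 100.0


def dissolved_co2(
    gas_co2: float, ph: float, sys: CarbonateSystem | None = None
) -> float:
    """Dissolved inorganic carbon (μmol) in equilibrium with headspace CO₂.

    The headspace amount fixes the partial pressure through the ideal-gas
    law; Henry's law then gives CO₂(aq), and the two carbonic-acid
    dissociations at the measured pH give bicarbonate and carbonate:

        p = n·R·T / V_gas
        [CO₂(aq)] = K_H · p
        [HCO₃⁻]  = K₁ · [CO₂(aq)] / [H⁺]
        [CO₃²⁻]  = K₂ · [HCO₃⁻] / [H⁺]

    The return is the summed species times the liquid (pore-water) volume.
    Strictly increasing in both pH and gas amount.
    """
    if sys is None:
        sys = CarbonateSystem()
    if gas_co2 < 0:
        raise ValueError(f"headspace CO2 cannot be negative: {gas_co2}")
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH outside (0, 14): {ph}")
    p_atm = gas_co2 * 1e-6 * R_L_ATM * sys.temperature_k / sys.v_gas_l
    co2_aq = sys.kh * p_atm                      # mol L⁻¹
    h = 10.0 ** (-ph)
    k1 = 10.0 ** (-sys.pk1)
    k2 = 10.0 ** (-sys.pk2)
    hco3 = k1 * co2_aq / h
    co3 = k2 * hco3 / h
    return (co2_aq + hco3 + co3) * sys.v_liquid_l * 1e6


def dissolved_to_gas_ratio(ph: float, sys: CarbonateSystem | None = None) -> float:
    """Equilibrium ratio dissolved-DIC : headspace CO₂ at a given pH.

    ``dissolved_co2`` is homogeneous of degree 1 in the gas amount, so this
    single number partitions any total CO₂ pool between phases.
    """
    return dissolved_co2(1.0, ph, sys)


def c13_recovery(
    gas_13ch4: float,
    gas_13co2: float,
    dissolved_13co2: float,
    c13_added: float,
) -> CarbonRecovery:
    """Total ¹³C in gaseous + dissolved products as percent of ¹³C added."""
    if c13_added <= 0:
        raise UndefinedRatioError("recovery undefined when no 13C was added")
    for name, v in (("gas_13ch4", gas_13ch4), ("gas_13co2", gas_13co2),
                    ("dissolved_13co2", dissolved_13co2)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative: {v}")
    raw = 100.0 * (gas_13ch4 + gas_13co2 + dissolved_13co2) / c13_added
    return CarbonRecovery(
        c13_added=c13_added,
        gas_13ch4=gas_13ch4,
        gas_13co2=gas_13co2,
        dissolved_13co2=dissolved_13co2,
        recovery=round_half_away(raw, 0),
        recovery_raw=raw,
    )


def suppression_percent(treatment_total: float, control_total: float) -> float:
    """Percent reduction of a gas pool relative to the unamended control.

    Negative values mean stimulation; they are returned as-is.
    """
    if control_total <= 0:
        raise UndefinedRatioError(
            "suppression undefined with non-positive control total"
        )
    return 100.0 * (control_total - treatment_total) / control_total


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

#: Column order used in summary tables: treatment-major, soil-minor.
TABLE_COLUMNS = [
    ("FER", "NF"), ("FER", "N"),
    ("GOE", "NF"), ("GOE", "N"),
    ("CTR", "NF"), ("CTR", "N"),
]


def electron_balance_table(
    columns: dict[tuple[str, str], tuple[float, float, float]],
):
    """Assemble a treatment × soil electron-balance table.

    ``columns`` maps (amendment, soil) to
    (fe2_formed μmol, acetate_consumed μmol, e_production meq).  Passing the
    measured electron production explicitly (rather than recomputing 8 ×
    rounded acetate) keeps the percentages faithful to unrounded raw data.
    Returns a pandas DataFrame with one row per quantity.
    """
    import pandas as pd

    rows = {
        "fe2_formation_umol": [],
        "acetate_consumption_umol": [],
        "electron_production_meq": [],
        "electron_to_fe_meq": [],
        "percent_to_fe": [],
    }
    labels = []
    for key in TABLE_COLUMNS:
        if key not in columns:
            continue
        fe2_formed, acetate_consumed, e_production = columns[key]
        bal = electron_balance(fe2_formed, e_production, acetate_consumed)
        labels.append(f"{key[0]}/{key[1]}")
        rows["fe2_formation_umol"].append(fe2_formed)
        rows["acetate_consumption_umol"].append(acetate_consumed)
        rows["electron_production_meq"].append(e_production)
        rows["electron_to_fe_meq"].append(bal.e_to_fe)
        rows["percent_to_fe"].append(bal.percent_to_fe)
    return pd.DataFrame(rows, index=labels).T


def c13_fate_table(
    columns: dict[tuple[str, str], tuple[float, float, float, float, float]],
    sys: CarbonateSystem | None = None,
):
    """Assemble a treatment × soil ¹³C-fate table.

    ``columns`` maps (amendment, soil) to
    (c13_added μmol, gas_13ch4 μmol, gas_13co2 μmol, ph, dissolved_13co2 or
    nan).  When the dissolved component is nan it is estimated from the
    gaseous ¹³CO₂ and the slurry pH through the carbonate system.
    """
    import pandas as pd

    rows = {
        "c13_added_umol": [],
        "gaseous_13ch4_umol": [],
        "gaseous_13co2_umol": [],
        "dissolved_13co2_umol": [],
        "ph": [],
        "c13_recovery_percent": [],
    }
    labels = []
    for key in TABLE_COLUMNS:
        if key not in columns:
            continue
        added, ch4, co2, ph, dis = columns[key]
        if dis is None or (isinstance(dis, float) and math.isnan(dis)):
            dis = dissolved_co2(co2, ph, sys)
        rec = c13_recovery(ch4, co2, dis, added)
        labels.append(f"{key[0]}/{key[1]}")
        rows["c13_added_umol"].append(added)
        rows["gaseous_13ch4_umol"].append(ch4)
        rows["gaseous_13co2_umol"].append(co2)
        rows["dissolved_13co2_umol"].append(dis)
        rows["ph"].append(ph)
        rows["c13_recovery_percent"].append(rec.recovery)
    return pd.DataFrame(rows, index=labels).T


def balance_from_series(
    spec: MicrocosmSpec,
    series: BiogeochemSeries,
    acetate_added_after_t0_umol_per_g: float = 0.0,
) -> ElectronBalance:
    """Electron balance for one vial straight from its measured time course.

    Per-gram increments are scaled to per-vial amounts with the dry mass in
    ``spec``; electron production is 8 × the measured acetate drawdown.
    """
    m = spec.soil_dry_mass_g
    fe2_formed = series.fe2_formed_umol_per_g() * m
    consumed = series.acetate_consumed_umol_per_g(acetate_added_after_t0_umol_per_g) * m
    return electron_balance(
        fe2_formed, acetate_electron_yield(consumed), acetate_consumed=consumed
    )


def recovery_from_series(
    spec: MicrocosmSpec,
    series: BiogeochemSeries,
    c13_added_umol: float,
    sys: CarbonateSystem | None = None,
) -> CarbonRecovery:
    """¹³C recovery for one vial from its final-day gas and pH measurements."""
    ch4_13 = labeled_gas_amount(series.ch4_total[-1], series.atom13_ch4[-1])
    co2_13 = labeled_gas_amount(series.co2_total[-1], series.atom13_co2[-1])
    dis_13 = dissolved_co2(co2_13, series.ph[-1], sys)
    return c13_recovery(ch4_13, co2_13, dis_13, c13_added_umol)
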