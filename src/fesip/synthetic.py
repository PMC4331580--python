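"""Seeded generators for microcosm, gradient and taxon-table data.

Every downstream stage of the pipeline is testable against known ground
truth produced here, with no external data.  The generators emulate the
study design: two soils (non-fertilized NF, N-fertilized N) × three
amendments (ferrihydrite FER, goethite GOE, unamended CTR) × two substrate
isotopes (¹³C / ¹²C acetate), sampled over a 4-day anoxic incubation.

Stoichiometric bookkeeping (noiseless core):

* acetate is fed in pulses (3.3 μmol g⁻¹ at days 0, 1.5 and 3) and decays
  first-order between pulses;
* a fraction ``f_fe`` of the theoretical electron production (8 e⁻ per
  acetate) flows into Fe(III) reduction: Fe(II) formed = 8 · a · f_fe;
* a fraction ``f_meth`` of consumed acetate is cleaved acetoclastically:
  CH₄ = a · f_meth, plus one CO₂ per CH₄;
* CO₂ = 2 · a · f_fe + a · f_meth plus a background mineralization term at
  natural ¹³C abundance; f_fe + f_meth ≤ 1 and the unaccounted substrate
  carbon is reported as the assimilated (biomass) pool;
* produced CO₂ partitions between headspace and pore water through the
  carbonate system at the slurry pH; the headspace part is what the series
  reports, mirroring what a gas chromatograph sees.

Gradient profiles are two-Gaussian mixtures over buoyant density: a light
band at ~1.782 g ml⁻¹ and, for ¹³C-fed bacteria, a proportion
``label_shift`` of the signal moved to a heavy band inside 1.791–1.806
g ml⁻¹.  Archaeal profiles never shift.  Taxon tables are multinomial draws
at fixed depth from baseline genus proportions, with designated assimilator
genera multiplied by per-amendment enrichment factors in labeled samples.

Gaussian/lognormal measurement noise is always added last, so the noiseless
core satisfies the mass balances exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from fesip.errors import ConfigError
from fesip.geochem import (
    BiogeochemSeries,
    CarbonateSystem,
    MicrocosmSpec,
    dissolved_to_gas_ratio,
)
from fesip.community import TaxonTable
from fesip.sip_gradient import GradientProfile

SAMPLING_DAYS = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0)

#: Electron share to Fe(III) per (amendment, soil), mirroring the measured
#: partition in the emulated study design.
DEFAULT_F_FE = {
    ("FER", "NF"): 0.74, ("FER", "N"): 0.84,
    ("GOE", "NF"): 0.14, ("GOE", "N"): 0.31,
    ("CTR", "NF"): 0.046, ("CTR", "N"): 0.11,
}
#: Acetoclastic share of consumed acetate; lower under FER (methanogenesis
#: suppressed by the competing Fe(III) respirers) and in the N soil.  Chosen
#: so the noiseless CH₄ totals show the study-scale suppression (~34% FER,
#: ~8% GOE vs CTR in each soil) while keeping f_fe + f_meth ≤ 1.
DEFAULT_F_METH = {
    ("FER", "NF"): 0.22, ("FER", "N"): 0.16,
    ("GOE", "NF"): 0.36, ("GOE", "N"): 0.27,
    ("CTR", "NF"): 0.40, ("CTR", "N"): 0.30,
}
#: First-order acetate consumption rate, d⁻¹ (near-complete FER consumption
#: between pulses).
DEFAULT_RATE = {"FER": 2.0, "GOE": 1.0, "CTR": 1.0}
#: Iron pools, μmol g⁻¹: (initial Fe(II), constant total extractable Fe).
DEFAULT_IRON_POOLS = {"FER": (75.0, 155.0), "GOE": (40.0, 75.0),
                      "CTR": (40.0, 63.0)}
DEFAULT_PH = {"FER": 7.7, "GOE": 7.6, "CTR": 7.5}

#: Baseline genus relative abundances (%) of heavy-fraction communities, and
#: per-amendment enrichment factors applied in labeled samples.
DEFAULT_TAXA_BASELINE = {
    "Geobacter": 2.4,
    "Dechloromonas": 3.0,
    "Clostridium": 4.0,
    "Pseudomonas": 2.0,
    "Solibacillus": 1.5,
    "Bacillus": 2.5,
    "Geothrix": 0.5,
    "Anaeromyxobacter": 0.8,
    "Desulfovibrio": 0.6,
    "Desulfobulbus": 0.4,
}
DEFAULT_ENRICHMENT = {
    "Geobacter": {"FER": 13.0, "GOE": 4.7},
    "Dechloromonas": {"FER": 4.0},
    "Clostridium": {"FER": 2.0, "GOE": 1.7},
    "Pseudomonas": {"FER": 3.0, "GOE": 3.1},
    "Solibacillus": {"FER": 5.0},
    "Bacillus": {"FER": 2.0},
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise magnitudes; zero everything for the noiseless core."""

    fe_sd: float = 1.5            # μmol g⁻¹, Gaussian on Fe(II)
    acetate_sd: float = 0.15      # μmol g⁻¹
    gas_sd: float = 0.3           # μmol per vial, CH₄ and CO₂
    atom_sd: float = 1.0          # atom-% points
    qpcr_lognormal_sd: float = 0.2  # sd of log copies per fraction
    bd_jitter_sd: float = 0.0005  # g ml⁻¹, run-to-run BD wobble

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SimulationParams:
    """Tunable knobs of the generators; defaults are the study conditions."""

    # substrate kinetics
    pulse_schedule: tuple = ((0.0, 3.3), (1.5, 3.3), (3.0, 3.3))  # (day, μmol g⁻¹)
    consumption_rate_per_day: float = 2.0
    f_fe: float = 0.74
    f_meth: float = 0.10
    atom13_substrate: float = 99.0     # labeled acetate
    atom13_background: float = 1.1     # natural abundance
    # Vial-level background mineralization of soil organic carbon at natural
    # abundance; the CO₂ term is large because unlabeled soil-C respiration
    # dominates the CO₂ pool and dilutes its atom-%13C to the ~20–30% scale,
    # while background methanogenesis keeps CH₄ atom-%13C near 80%.
    background_ch4_umol_per_day: float = 0.4
    background_co2_umol_per_day: float = 30.0
    fe2_initial_umol_per_g: float = 75.0
    total_fe_umol_per_g: float = 155.0
    ph: float = 7.7
    time_days: tuple = SAMPLING_DAYS
    carbonate: CarbonateSystem = field(default_factory=CarbonateSystem)
    # gradient geometry
    light_center: float = 1.782
    heavy_center: float = 1.7985
    band_sd: float = 0.004
    n_fractions: int = 14
    bd_min: float = 1.77
    bd_max: float = 1.82
    label_shift: float = 0.6
    archaea_amplitude: float = 0.3     # relative to bacterial peak
    # taxon tables
    taxa_baseline: dict = field(default_factory=lambda: dict(DEFAULT_TAXA_BASELINE))
    enrichment: dict = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_ENRICHMENT.items()}
    )
    depth: int = 3990
    fractions_sequenced: tuple = (5, 6, 7)
    # noise
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self):
        if self.f_fe < 0 or self.f_meth < 0 or self.f_fe + self.f_meth > 1:
            raise ConfigError("need f_fe, f_meth >= 0 and f_fe + f_meth <= 1")
        if not 0 <= self.label_shift <= 1:
            raise ConfigError("label_shift must be a proportion")
        if self.consumption_rate_per_day <= 0:
            raise ConfigError("consumption rate must be positive")
        if self.depth <= 0:
            raise ConfigError("sequencing depth must be positive")
        horizon = max(self.time_days)
        for day, amount in self.pulse_schedule:
            if day < 0 or day > horizon:
                raise ConfigError(
                    f"pulse at day {day} outside simulation horizon [0, {horizon}]"
                )
            if amount <= 0:
                raise ConfigError("pulse amounts must be positive")
        if not self.bd_min < self.light_center < self.heavy_center < self.bd_max:
            raise ConfigError("band centers must lie inside the BD grid span")

    def with_treatment(self, amendment: str, soil: str) -> "SimulationParams":
        """Copy with the per-treatment defaults for one (amendment, soil)."""
        import dataclasses

        fe2_0, total_fe = DEFAULT_IRON_POOLS[amendment]
        return dataclasses.replace(
            self,
            f_fe=DEFAULT_F_FE[(amendment, soil)],
            f_meth=DEFAULT_F_METH[(amendment, soil)],
            consumption_rate_per_day=DEFAULT_RATE[amendment],
            fe2_initial_umol_per_g=fe2_0,
            total_fe_umol_per_g=total_fe,
            ph=DEFAULT_PH[amendment],
        )


@dataclass
class GroundTruth:
    """Realized quantities recorded alongside every generated dataset."""

    seed: int
    f_fe: float | None = None
    f_meth: float | None = None
    percent_to_fe: float | None = None
    acetate_consumed_umol: float | None = None       # per vial
    fe2_formed_umol: float | None = None             # per vial
    ch4_total_umol: float | None = None
    co2_total_umol: float | None = None              # headspace + dissolved
    c13_added_umol: float | None = None
    c13_gas_umol: float | None = None                # ¹³CH₄ + ¹³CO₂ all phases
    c13_assimilated_umol: float | None = None
    label_shift: float | None = None
    expected_heavy_mass_fraction: float | None = None
    enrichment: dict | None = None                   # genus -> amendment -> realized
    expected_proportions: dict | None = None         # sample kind -> genus -> prop

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


# ---------------------------------------------------------------------------
# microcosm time courses
# ---------------------------------------------------------------------------

def _acetate_course(params: SimulationParams, t: float) -> tuple[float, float]:
    """(acetate remaining, cumulative consumed) at time ``t``, μmol g⁻¹.

    Piecewise first-order decay with instantaneous pulses; measurements at a
    pulse time see the post-pulse pool (the replenished substrate).
    """
    k = params.consumption_rate_per_day
    pulses = sorted(params.pulse_schedule)
    pool = 0.0
    added = 0.0
    t_prev = 0.0
    for day, amount in pulses:
        if day > t:
            break
        pool *= math.exp(-k * (day - t_prev))
        pool += amount
        added += amount
        t_prev = day
    pool *= math.exp(-k * (t - t_prev))
    return pool, added - pool


def simulate_microcosm(
    spec: MicrocosmSpec,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> tuple[BiogeochemSeries, GroundTruth]:
    """One vial's geochemical time course plus its generating truth."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mass = spec.soil_dry_mass_g
    labeled = spec.isotope == "C13"
    atom_sub = params.atom13_substrate if labeled else params.atom13_background
    atom_bg = params.atom13_background
    ratio = dissolved_to_gas_ratio(params.ph, params.carbonate)

    times, fe2, acetate, ch4, co2_gas = [], [], [], [], []
    a13_ch4, a13_co2, phs = [], [], []
    for t in params.time_days:
        pool, consumed = _acetate_course(params, t)
        times.append(t)
        acetate.append(pool)
        fe2.append(params.fe2_initial_umol_per_g + 8.0 * params.f_fe * consumed)
        c_vial = consumed * mass  # μmol acetate per vial
        ch4_sub = params.f_meth * c_vial
        ch4_bg = params.background_ch4_umol_per_day * t
        co2_sub = (2.0 * params.f_fe + params.f_meth) * c_vial
        co2_bg = params.background_co2_umol_per_day * t
        ch4_tot = ch4_sub + ch4_bg
        co2_tot = co2_sub + co2_bg
        co2_head = co2_tot / (1.0 + ratio)
        ch4.append(ch4_tot)
        co2_gas.append(co2_head)
        a13_ch4.append(
            (atom_sub * ch4_sub + atom_bg * ch4_bg) / ch4_tot
            if ch4_tot > 0 else atom_bg
        )
        a13_co2.append(
            (atom_sub * co2_sub + atom_bg * co2_bg) / co2_tot
            if co2_tot > 0 else atom_bg
        )
        phs.append(params.ph)

    n = len(times)
    noise = params.noise
    total_fe = [params.total_fe_umol_per_g] * n
    fe2_noisy = np.clip(
        np.asarray(fe2) + rng.normal(0, noise.fe_sd, n) if noise.fe_sd else fe2,
        0.0, params.total_fe_umol_per_g,
    )
    acetate_noisy = np.clip(
        np.asarray(acetate) + rng.normal(0, noise.acetate_sd, n)
        if noise.acetate_sd else acetate, 0.0, None,
    )
    ch4_noisy = np.clip(
        np.asarray(ch4) + rng.normal(0, noise.gas_sd, n) if noise.gas_sd else ch4,
        0.0, None,
    )
    co2_noisy = np.clip(
        np.asarray(co2_gas) + rng.normal(0, noise.gas_sd, n)
        if noise.gas_sd else co2_gas, 0.0, None,
    )
    a13_ch4_noisy = np.clip(
        np.asarray(a13_ch4) + rng.normal(0, noise.atom_sd, n)
        if noise.atom_sd else a13_ch4, 0.0, 100.0,
    )
    a13_co2_noisy = np.clip(
        np.asarray(a13_co2) + rng.normal(0, noise.atom_sd, n)
        if noise.atom_sd else a13_co2, 0.0, 100.0,
    )

    series = BiogeochemSeries(
        time_days=list(times),
        fe2=list(map(float, fe2_noisy)),
        total_fe=total_fe,
        acetate=list(map(float, acetate_noisy)),
        ch4_total=list(map(float, ch4_noisy)),
        co2_total=list(map(float, co2_noisy)),
        atom13_ch4=list(map(float, a13_ch4_noisy)),
        atom13_co2=list(map(float, a13_co2_noisy)),
        ph=phs,
    )

    _, consumed_final = _acetate_course(params, params.time_days[-1])
    c_vial = consumed_final * mass
    total_added = sum(a for _, a in params.pulse_schedule) * mass
    frac_sub = atom_sub / 100.0
    c13_added = 2.0 * total_added * frac_sub
    ch4_sub = params.f_meth * c_vial
    co2_sub = (2.0 * params.f_fe + params.f_meth) * c_vial
    c13_gas = (ch4_sub + co2_sub) * frac_sub
    c13_consumed = 2.0 * c_vial * frac_sub
    truth = GroundTruth(
        seed=params.seed,
        f_fe=params.f_fe,
        f_meth=params.f_meth,
        percent_to_fe=100.0 * params.f_fe,
        acetate_consumed_umol=c_vial,
        fe2_formed_umol=8.0 * params.f_fe * c_vial,
        ch4_total_umol=ch4_sub + params.background_ch4_umol_per_day * times[-1],
        co2_total_umol=co2_sub + params.background_co2_umol_per_day * times[-1],
        c13_added_umol=c13_added,
        c13_gas_umol=c13_gas,
        c13_assimilated_umol=c13_consumed - c13_gas,
    )
    return series, truth


# ---------------------------------------------------------------------------
# density-gradient profiles
# ---------------------------------------------------------------------------

def _gaussian(bd: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((bd - center) / sd) ** 2)


def expected_heavy_mass_fraction(
    params: SimulationParams, shift: float, heavy_lo: float, heavy_hi: float
) -> float:
    """Analytic (continuous-density) heavy-window mass share of a shifted
    two-Gaussian profile — the error-function integral the discrete grid
    approximates."""
    from math import erf, sqrt

    def band_mass(center):
        z = lambda x: (x - center) / (params.band_sd * sqrt(2.0))
        return 0.5 * (erf(z(heavy_hi)) - erf(z(heavy_lo)))

    return (1.0 - shift) * band_mass(params.light_center) + shift * band_mass(
        params.heavy_center
    )


def simulate_gradient(
    params: SimulationParams,
    isotope: str,
    rng: np.random.Generator | None = None,
    treatment: str = "sim",
) -> tuple[GradientProfile, GradientProfile]:
    """(bacterial, archaeal) gradient profiles for one treatment.

    Fraction 1 is the heaviest (gradients are tapped from the vial bottom);
    buoyant density decreases with fraction number.  For a ¹³C-fed vial a
    proportion ``label_shift`` of the bacterial signal sits in the heavy
    band; archaea stay entirely light regardless of isotope.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    bd = np.linspace(params.bd_max, params.bd_min, params.n_fractions)
    if params.noise.bd_jitter_sd > 0:
        bd = bd + rng.normal(0, params.noise.bd_jitter_sd, len(bd))
        bd = np.sort(bd)[::-1]  # keep the tap order strictly monotone
    shift = params.label_shift if isotope == "C13" else 0.0

    bact = (1.0 - shift) * _gaussian(bd, params.light_center, params.band_sd) \
        + shift * _gaussian(bd, params.heavy_center, params.band_sd)
    arch = params.archaea_amplitude * _gaussian(
        bd, params.light_center, params.band_sd
    )
    scale = 1e8  # rRNA copies at the band peak, qPCR-realistic order
    bact = bact * scale
    arch = arch * scale
    if params.noise.qpcr_lognormal_sd > 0:
        bact = bact * rng.lognormal(0, params.noise.qpcr_lognormal_sd, len(bd))
        arch = arch * rng.lognormal(0, params.noise.qpcr_lognormal_sd, len(bd))
    idx = np.arange(1, params.n_fractions + 1)
    make = lambda domain, copies: GradientProfile(
        treatment=f"{treatment}-{isotope}",
        domain=domain,
        fraction_index=idx,
        bd=bd,
        copies=copies,
    )
    return make("Bacteria", bact), make("Archaea", arch)


# ---------------------------------------------------------------------------
# taxon count tables
# ---------------------------------------------------------------------------

def _sample_proportions(
    params: SimulationParams, amendment: str, labeled: bool
) -> dict[str, float]:
    """Expected genus proportions (0–1) for one sample; the unassigned
    remainder goes to an 'other' pool, so enriching one genus does not
    dilute the rest."""
    props = {}
    for genus, baseline_pct in params.taxa_baseline.items():
        p = baseline_pct / 100.0
        if labeled:
            p *= params.enrichment.get(genus, {}).get(amendment, 1.0)
        props[genus] = p
    named = sum(props.values())
    if named > 1.0:
        props = {g: p / named for g, p in props.items()}
        named = 1.0
    props["other"] = 1.0 - named
    return props


def simulate_taxon_table(
    params: SimulationParams,
    soil: str = "NF",
    rng: np.random.Generator | None = None,
) -> tuple[TaxonTable, GroundTruth]:
    """Genus count table for one soil's heavy-fraction samples.

    Samples cover amendments × isotopes × the sequenced fractions (three per
    treatment); counts are multinomial at ``params.depth`` from the
    enrichment-adjusted proportions.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    genera = list(params.taxa_baseline) + ["other"]
    rows, meta_rows, index = [], [], []
    expected: dict[str, dict[str, float]] = {}
    for amendment in ("FER", "GOE", "CTR"):
        for isotope in ("C13", "C12"):
            props = _sample_proportions(params, amendment, isotope == "C13")
            expected[f"{amendment}-{isotope}"] = props
            p = np.array([props[g] for g in genera])
            for frac in params.fractions_sequenced:
                index.append(f"{soil}-{amendment}-{isotope}-F{frac}")
                rows.append(rng.multinomial(params.depth, p))
                meta_rows.append({
                    "soil": soil, "amendment": amendment,
                    "isotope": isotope, "fraction": frac,
                })
    counts = pd.DataFrame(rows, index=index, columns=genera)
    metadata = pd.DataFrame(meta_rows, index=index)
    realized = {
        genus: {
            amd: (expected[f"{amd}-C13"][genus]
                  / expected["CTR-C13"][genus])
            for amd in ("FER", "GOE")
            if expected["CTR-C13"][genus] > 0
        }
        for genus in params.taxa_baseline
    }
    truth = GroundTruth(
        seed=params.seed,
        enrichment=realized,
        expected_proportions=expected,
    )
    return TaxonTable(counts, metadata), truth
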