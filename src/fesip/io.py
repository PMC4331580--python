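"""TSV schemas, run configuration and the end-to-end pipeline.

Canonical interchange format is UTF-8 TSV with a header row and '.' decimal
separator.  Three input schemas are defined:

* **measurements** (long format): ``microcosm_id, time_days, analyte, value,
  unit`` with one row per reading;
* **fractions**: ``microcosm_id, domain, fraction_index,
  buoyant_density_g_per_ml, copies``;
* **taxa**: a samples × genera count matrix plus a sample-metadata table
  ``sample_id, soil, amendment, isotope, fraction``.

``run_all`` chains simulate → electron/¹³C balances → gradient labeling →
community screening and writes treatment × soil summary tables, evidence
JSON and a run log recording every defaulted parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fesip import community, geochem, sip_gradient, synthetic
from fesip.errors import ConfigError, FesipError, SchemaError

log = logging.getLogger("fesip")

#: analyte name -> accepted unit label in measurement files
MEASUREMENT_UNITS = {
    "fe2": "umol_per_g",
    "total_fe": "umol_per_g",
    "acetate": "umol_per_g",
    "ch4_total": "umol",
    "co2_total": "umol",
    "atom13_ch4": "percent",
    "atom13_co2": "percent",
    "ph": "dimensionless",
}
_SERIES_FIELDS = list(MEASUREMENT_UNITS)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_metadata(path) -> dict[str, geochem.MicrocosmSpec]:
    """Microcosm metadata TSV keyed by microcosm_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"microcosm_id", "soil", "amendment", "isotope"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}", path=path)
    specs = {}
    defaults = geochem.MicrocosmSpec("NF", "CTR")
    for line, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            specs[d["microcosm_id"]] = geochem.MicrocosmSpec(
                soil=d["soil"], amendment=d["amendment"], isotope=d["isotope"],
                slurry_volume_ml=float(d.get("slurry_volume_ml",
                                             defaults.slurry_volume_ml)),
                headspace_volume_ml=float(d.get("headspace_volume_ml",
                                                defaults.headspace_volume_ml)),
                soil_dry_mass_g=float(d.get("soil_dry_mass_g",
                                            defaults.soil_dry_mass_g)),
                fe_added_umol_per_g=float(d.get("fe_added_umol_per_g", 0.0)),
                temperature_k=float(d.get("temperature_k",
                                          defaults.temperature_k)),
            )
        except (ConfigError, ValueError) as exc:
            raise SchemaError(str(exc), path=path, line=line) from exc
    return specs


def write_metadata(specs: dict[str, geochem.MicrocosmSpec], path) -> None:
    rows = [dict(microcosm_id=mid, **dataclasses.asdict(s))
            for mid, s in specs.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_measurements(path) -> dict[str, geochem.BiogeochemSeries]:
    """Long-format measurement TSV -> one time series per microcosm."""
    df = pd.read_csv(path, sep="\t")
    required = {"microcosm_id", "time_days", "analyte", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}", path=path)
    for pos, row in df.iterrows():
        line = pos + 2  # header + 1-based
        if row["analyte"] not in MEASUREMENT_UNITS:
            raise SchemaError(
                f"unknown analyte {row['analyte']!r}", path=path,
                line=line, column="analyte",
            )
        if row["unit"] != MEASUREMENT_UNITS[row["analyte"]]:
            raise SchemaError(
                f"analyte {row['analyte']!r} expects unit "
                f"{MEASUREMENT_UNITS[row['analyte']]!r}, got {row['unit']!r}",
                path=path, line=line, column="unit",
            )
    out = {}
    for mid, grp in df.groupby("microcosm_id", sort=False):
        wide = grp.pivot_table(
            index="time_days", columns="analyte", values="value", sort=True
        )
        missing_analytes = set(_SERIES_FIELDS) - set(wide.columns)
        if missing_analytes or wide.isna().any().any():
            raise SchemaError(
                f"microcosm {mid!r} lacks complete series for "
                f"{sorted(missing_analytes) or 'some time points'}",
                path=path,
            )
        out[mid] = geochem.BiogeochemSeries(
            time_days=list(wide.index),
            **{f: list(wide[f]) for f in _SERIES_FIELDS},
        )
    return out


def write_measurements(series: dict[str, geochem.BiogeochemSeries], path) -> None:
    rows = []
    for mid, s in series.items():
        for i, t in enumerate(s.time_days):
            for analyte, unit in MEASUREMENT_UNITS.items():
                rows.append({
                    "microcosm_id": mid, "time_days": t, "analyte": analyte,
                    "value": getattr(s, analyte)[i], "unit": unit,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fractions(path) -> dict[tuple[str, str], sip_gradient.GradientProfile]:
    """Fraction TSV -> {(microcosm_id, domain): GradientProfile}."""
    df = pd.read_csv(path, sep="\t")
    required = {"microcosm_id", "domain", "fraction_index",
                "buoyant_density_g_per_ml", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}", path=path)
    neg = df.index[df["copies"] < 0]
    if len(neg) > 0:
        raise SchemaError(
            "negative copies value", path=path, line=int(neg[0]) + 2,
            column="copies",
        )
    out = {}
    for (mid, domain), grp in df.groupby(["microcosm_id", "domain"], sort=False):
        try:
            out[(mid, domain)] = sip_gradient.GradientProfile(
                treatment=mid, domain=domain,
                fraction_index=grp["fraction_index"].values,
                bd=grp["buoyant_density_g_per_ml"].values,
                copies=grp["copies"].values,
            )
        except ValueError as exc:
            raise SchemaError(str(exc), path=path) from exc
    return out


def write_fractions(
    profiles: dict[tuple[str, str], sip_gradient.GradientProfile], path
) -> None:
    rows = []
    for (mid, domain), p in profiles.items():
        for i, bd, c in zip(p.fraction_index, p.bd, p.copies):
            rows.append({
                "microcosm_id": mid, "domain": domain, "fraction_index": i,
                "buoyant_density_g_per_ml": bd, "copies": c,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_taxa(counts_path, meta_path) -> community.TaxonTable:
    """Count matrix + sample metadata -> TaxonTable."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    try:
        return community.TaxonTable(counts, meta)
    except ValueError as exc:
        raise SchemaError(str(exc), path=counts_path) from exc


def write_taxa(table: community.TaxonTable, counts_path, meta_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    table.metadata.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    outdir: Path = Path("fesip_out")
    seed: int = 0
    soils: tuple = ("NF", "N")
    alpha: float = 0.05
    shift_threshold: float = 0.15
    c13_added_umol_per_g: float = 9.9   # three 3.3 μmol g⁻¹ pulses
    carbonate: geochem.CarbonateSystem = field(
        default_factory=geochem.CarbonateSystem
    )
    windows: sip_gradient.DensityWindows = field(
        default_factory=sip_gradient.DensityWindows
    )
    params: synthetic.SimulationParams = field(
        default_factory=synthetic.SimulationParams
    )
    # optional measured inputs; when absent the synthetic generator runs
    measurements_path: Path | None = None
    metadata_path: Path | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON (YAML is a JSON superset)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "carbonate" in raw:
            kwargs["carbonate"] = geochem.CarbonateSystem(**raw.pop("carbonate"))
        if "windows" in raw:
            kwargs["windows"] = sip_gradient.DensityWindows(**raw.pop("windows"))
        if "params" in raw:
            p = raw.pop("params")
            if "noise" in p:
                p["noise"] = synthetic.NoiseModel(**p["noise"])
            if "pulse_schedule" in p:
                p["pulse_schedule"] = tuple(map(tuple, p["pulse_schedule"]))
            kwargs["params"] = synthetic.SimulationParams(**p)
        for key in ("outdir", "measurements_path", "metadata_path"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        cfg = cls(**kwargs)
        for p in (cfg.measurements_path, cfg.metadata_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input path does not exist: {p}")
        return cfg


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    """Generate the study grid and write the interchange files."""
    root = np.random.SeedSequence(cfg.seed)
    keys = [(soil, amd, iso) for soil in cfg.soils
            for amd in geochem.AMENDMENTS for iso in geochem.ISOTOPES]
    seeds = root.spawn(len(keys) + len(cfg.soils))
    specs, series, truths, gradients = {}, {}, {}, {}
    for (soil, amd, iso), ss in zip(keys, seeds):
        spec = geochem.MicrocosmSpec(
            soil=soil, amendment=amd, isotope=iso,
            fe_added_umol_per_g=0.0 if amd == "CTR" else 140.0,
        )
        params = cfg.params.with_treatment(amd, soil)
        rng = np.random.default_rng(ss)
        s, t = synthetic.simulate_microcosm(spec, params, rng)
        bact, arch = synthetic.simulate_gradient(
            params, iso, rng, treatment=f"{soil}-{amd}"
        )
        mid = spec.microcosm_id
        specs[mid], series[mid], truths[mid] = spec, s, t
        gradients[(mid, "Bacteria")] = bact
        gradients[(mid, "Archaea")] = arch
    tables = {}
    for soil, ss in zip(cfg.soils, seeds[len(keys):]):
        tables[soil], truths[f"taxa-{soil}"] = synthetic.simulate_taxon_table(
            cfg.params, soil=soil, rng=np.random.default_rng(ss)
        )
    write_metadata(specs, outdir / "metadata.tsv")
    write_measurements(series, outdir / "measurements.tsv")
    write_fractions(gradients, outdir / "fractions.tsv")
    for soil, table in tables.items():
        write_taxa(table, outdir / f"taxa_{soil}.tsv",
                   outdir / f"taxa_{soil}_meta.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in truths.items()}, fh, indent=1,
                  default=float)
    return {"specs": specs, "series": series, "gradients": gradients,
            "tables": tables, "truths": truths}


def _stage_geochem(cfg: RunConfig, outdir: Path, bundle: dict) -> list[str]:
    """Electron-balance and ¹³C-fate tables from the labeled vials."""
    warnings_out = []
    e_cols, c_cols = {}, {}
    for (amd, soil) in geochem.TABLE_COLUMNS:
        if soil not in cfg.soils:
            continue
        mid = f"{soil}-{amd}-C13"
        spec, s = bundle["specs"][mid], bundle["series"][mid]
        added_after_t0 = cfg.c13_added_umol_per_g - cfg.params.pulse_schedule[0][1]
        bal = geochem.balance_from_series(spec, s, added_after_t0)
        e_cols[(amd, soil)] = (bal.fe2_formed, bal.acetate_consumed,
                               bal.e_production)
        if bal.exceeds_production:
            warnings_out.append(
                f"{mid}: electron partition {bal.percent_to_fe_raw:.1f}% "
                "exceeds acetate-derived production"
            )
        c13_added = (2.0 * cfg.c13_added_umol_per_g * spec.soil_dry_mass_g
                     * cfg.params.atom13_substrate / 100.0)
        ch4_13 = geochem.labeled_gas_amount(s.ch4_total[-1], s.atom13_ch4[-1])
        co2_13 = geochem.labeled_gas_amount(s.co2_total[-1], s.atom13_co2[-1])
        c_cols[(amd, soil)] = (c13_added, ch4_13, co2_13, s.ph[-1], float("nan"))
    geochem.electron_balance_table(e_cols).to_csv(
        outdir / "table3.tsv", sep="\t", index_label="quantity"
    )
    geochem.c13_fate_table(c_cols, cfg.carbonate).to_csv(
        outdir / "table2.tsv", sep="\t", index_label="quantity"
    )
    return warnings_out


def _stage_gradient(cfg: RunConfig, outdir: Path, bundle: dict) -> list[str]:
    """Normalization, labeling evidence and heavy-fraction selection."""
    warnings_out = []
    evidence, normalized, selected_rows = {}, {}, []
    for soil in cfg.soils:
        for amd in geochem.AMENDMENTS:
            for domain in ("Bacteria", "Archaea"):
                lab = bundle["gradients"][(f"{soil}-{amd}-C13", domain)]
                unl = bundle["gradients"][(f"{soil}-{amd}-C12", domain)]
                ev = sip_gradient.labeling_evidence(
                    lab, unl, cfg.windows, cfg.shift_threshold
                )
                evidence[f"{soil}-{amd}-{domain}"] = {
                    "heavy_mass_fraction_labeled": ev.heavy_mass_fraction_labeled,
                    "heavy_mass_fraction_unlabeled": ev.heavy_mass_fraction_unlabeled,
                    "difference": ev.difference,
                    "threshold": ev.threshold,
                    "shifted": ev.shifted,
                }
                norm = sip_gradient.normalize_profile(lab)
                normalized[(f"{soil}-{amd}-C13", domain)] = norm
                for idx in sip_gradient.select_heavy_fractions(norm, cfg.windows):
                    selected_rows.append({
                        "microcosm_id": f"{soil}-{amd}-C13", "domain": domain,
                        "fraction_index": idx,
                    })
    with open(outdir / "labeling_evidence.json", "w") as fh:
        json.dump(evidence, fh, indent=1)
    write_fractions(normalized, outdir / "normalized_profiles.tsv")
    pd.DataFrame(selected_rows).to_csv(
        outdir / "selected_fractions.tsv", sep="\t", index=False
    )
    return warnings_out


def _stage_community(cfg: RunConfig, outdir: Path, bundle: dict) -> list[str]:
    """Assimilator screen, treatment effects and iron-reducer summary."""
    warnings_out = []
    screens, effects, field_rows = [], [], []
    ref = community.IronReducerReference()
    for soil, table in bundle["tables"].items():
        for amd in geochem.AMENDMENTS:
            scr = community.screen_table(table, amd, soil, alpha=cfg.alpha)
            scr.insert(0, "soil", soil)
            scr.insert(1, "amendment", amd)
            screens.append(scr.reset_index())
        eff = community.treatment_effects(table, soil)
        eff.insert(0, "soil", soil)
        effects.append(eff.reset_index(names="genus"))
        reducers = community.filter_iron_reducers(table, ref)
        if reducers.genera:
            # field-style summary: mean abundance of reducer genera per soil,
            # as percent of the full community
            rel_full = community.relative_abundance(table)
            mean_rel = rel_full[reducers.genera].mean()
            for genus, val in mean_rel.items():
                field_rows.append({"soil": soil, "genus": genus,
                                   "mean_rel_abundance": val})
        else:
            warnings_out.append(f"{soil}: no putative iron reducers in table")
    pd.concat(screens).to_csv(outdir / "screening_report.tsv", sep="\t",
                              index=False)
    pd.concat(effects).to_csv(outdir / "fig5_net_change.tsv", sep="\t",
                              index=False)
    pd.DataFrame(field_rows).to_csv(outdir / "fig6_field_abundance.tsv",
                                    sep="\t", index=False)
    return warnings_out


def run_all(cfg: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Deterministic given ``cfg.seed``.  Any stage failure removes the partial
    output directory and re-raises with the stage name.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    warnings_out = []
    stage = "simulate"
    try:
        log.info("seed=%d outdir=%s", cfg.seed, outdir)
        log.info("defaults: carbonate=%s", cfg.carbonate)
        log.info("defaults: windows=%s", cfg.windows)
        log.info("defaults: soil_dry_mass_g=3.0 (derived, per-vial/per-gram "
                 "Fe(II) ratio); alpha=%.3f shift_threshold=%.2f",
                 cfg.alpha, cfg.shift_threshold)
        bundle = _stage_simulate(cfg, outdir)
        stage = "geochem"
        warnings_out += _stage_geochem(cfg, outdir, bundle)
        stage = "gradient"
        warnings_out += _stage_gradient(cfg, outdir, bundle)
        stage = "community"
        warnings_out += _stage_community(cfg, outdir, bundle)
        with open(outdir / "warnings.json", "w") as fh:
            json.dump(warnings_out, fh, indent=1)
        for w in warnings_out:
            log.warning(w)
        log.info("run complete")
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        log.removeHandler(handler)
        handler.close()
        shutil.rmtree(outdir, ignore_errors=True)
        raise FesipError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        if handler in log.handlers:
            log.removeHandler(handler)
            handler.close()
    return outdir
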