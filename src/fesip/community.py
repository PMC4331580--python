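"""Genus-level community analysis of heavy-fraction amplicon counts.

Sequencing the pooled heavy gradient fractions yields, per fraction-sample,
counts of 16S reads classified to genus.  This module computes relative
abundances, screens genera for ¹³C assimilation (significantly higher
relative abundance in the labeled than the parallel unlabeled treatment,
one-sided exact permutation test at α = 0.05), expresses treatment effects
as net proportional change (percentage points vs the unamended control) and
fold change, and restricts tables to putative dissimilatory iron reducers —
a review-derived genus list used because Fe(III) reduction has no universal
functional marker gene.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fesip.errors import UndefinedRatioError

#: Genera treated as putative dissimilatory Fe(III) reducers, from published
#: reviews of dissimilatory iron-reducing microorganisms.
DEFAULT_IRON_REDUCER_GENERA: dict[str, str] = {
    "Geobacter": "dissimilatory Fe(III)-reducer reviews",
    "Geothrix": "dissimilatory Fe(III)-reducer reviews",
    "Desulfobulbus": "dissimilatory Fe(III)-reducer reviews",
    "Clostridium": "fermentative Fe(III) reduction reports",
    "Anaeromyxobacter": "dissimilatory Fe(III)-reducer reviews",
    "Desulfovibrio": "dissimilatory Fe(III)-reducer reviews",
    "Desulfosporosinus": "dissimilatory Fe(III)-reducer reviews",
    "Dechloromonas": "Fe(III)-reduction enrichment reports",
    "Pseudomonas": "fermentative/respiratory Fe(III) reduction reports",
    "Desulfitobacterium": "dissimilatory Fe(III)-reducer reviews",
    "Acidiphilium": "dissimilatory Fe(III)-reducer reviews",
}


@dataclass(frozen=True)
class IronReducerReference:
    """Reference list of putative iron-reducer genera with citation tags."""

    genera: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_IRON_REDUCER_GENERA)
    )

    def __post_init__(self):
        if len(set(self.genera)) != len(self.genera):
            raise ValueError("reference genus names must be unique")

    @classmethod
    def from_file(cls, path) -> "IronReducerReference":
        """Read a plain-text list: one genus per line, optional tab-separated
        citation tag, '#' comments allowed."""
        genera: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                genera[parts[0]] = parts[1] if len(parts) > 1 else ""
        return cls(genera=genera)


class TaxonTable:
    """Counts of classified sequences per genus per fraction-sample.

    ``counts`` is a samples × genera integer DataFrame; ``metadata`` maps each
    sample (index-aligned) to its soil, amendment, isotope and gradient
    fraction.
    """

    REQUIRED_META = ("soil", "amendment", "isotope", "fraction")

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        counts = counts.copy()
        if counts.shape[1] < 1:
            raise ValueError("taxon table needs at least one genus column")
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("counts must be integers")
        missing = set(counts.index) - set(metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in self.REQUIRED_META:
            if col not in metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        self.counts = counts.astype(int)
        self.metadata = metadata.loc[counts.index]

    @property
    def genera(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, mask) -> "TaxonTable":
        return TaxonTable(self.counts.loc[mask], self.metadata.loc[mask])

    def samples_for(self, amendment: str, isotope: str, soil: str | None = None):
        meta = self.metadata
        mask = (meta["amendment"] == amendment) & (meta["isotope"] == isotope)
        if soil is not None:
            mask &= meta["soil"] == soil
        return list(meta.index[mask])


def relative_abundance(table: TaxonTable) -> pd.DataFrame:
    """Per-sample genus percentages; every retained row sums to 100.

    Samples with zero total counts carry no compositional information and
    are dropped with a warning.
    """
    totals = table.counts.sum(axis=1)
    empty = totals[totals == 0].index
    if len(empty) > 0:
        warnings.warn(
            f"excluding zero-count samples: {list(empty)}", stacklevel=2
        )
    kept = table.counts.loc[totals > 0]
    return 100.0 * kept.div(kept.sum(axis=1), axis=0)


def permutation_pvalue_one_sided(
    labeled: np.ndarray, unlabeled: np.ndarray, max_exact: int = 20000
) -> float:
    """Exact one-sided permutation p-value for mean(labeled) > mean(unlabeled).

    All assignments of the pooled values into groups of the original sizes
    are enumerated; the p-value is the share of assignments whose difference
    of means is at least the observed one (the identity assignment counts,
    so p ≥ 1/#assignments).  Identical pooled values give p = 1.  For group
    sizes beyond ``max_exact`` assignments a seeded Monte-Carlo fallback with
    10⁴ draws is used.
    """
    labeled = np.asarray(labeled, dtype=float)
    unlabeled = np.asarray(unlabeled, dtype=float)
    if len(labeled) < 2 or len(unlabeled) < 2:
        raise ValueError("need at least 2 replicates per group")
    pooled = np.concatenate([labeled, unlabeled])
    n_lab = len(labeled)
    n_tot = len(pooled)
    observed = labeled.mean() - unlabeled.mean()
    n_assign = math.comb(n_tot, n_lab)
    # tolerance guards against float jitter when permuted sums tie the observed
    tol = 1e-12 * max(1.0, float(np.max(np.abs(pooled))))
    if n_assign <= max_exact:
        count = 0
        for idx in itertools.combinations(range(n_tot), n_lab):
            sel = np.zeros(n_tot, dtype=bool)
            sel[list(idx)] = True
            diff = pooled[sel].mean() - pooled[~sel].mean()
            if diff >= observed - tol:
                count += 1
        return count / n_assign
    rng = np.random.default_rng(0)
    n_mc = 10_000
    count = 1  # identity assignment
    for _ in range(n_mc):
        perm = rng.permutation(n_tot)
        diff = pooled[perm[:n_lab]].mean() - pooled[perm[n_lab:]].mean()
        if diff >= observed - tol:
            count += 1
    return count / (n_mc + 1)


@dataclass(frozen=True)
class ScreenResult:
    """Per-genus outcome of the assimilator screen."""

    genus: str
    mean_rel_labeled: float
    mean_rel_unlabeled: float
    p_value: float
    assimilator: bool


def assimilator_screen(
    labeled_reps,
    unlabeled_reps,
    alpha: float = 0.05,
    genus: str = "",
) -> ScreenResult:
    """Flag a genus as a ¹³C assimilator.

    A genus qualifies when its relative abundance is significantly higher in
    the labeled heavy fractions than in the corresponding unlabeled ones:
    one-sided exact permutation test with p ≤ α *and* a higher labeled mean.
    """
    labeled = np.asarray(labeled_reps, dtype=float)
    unlabeled = np.asarray(unlabeled_reps, dtype=float)
    p = permutation_pvalue_one_sided(labeled, unlabeled)
    higher = labeled.mean() > unlabeled.mean()
    return ScreenResult(
        genus=genus,
        mean_rel_labeled=float(labeled.mean()),
        mean_rel_unlabeled=float(unlabeled.mean()),
        p_value=p,
        assimilator=bool(p <= alpha and higher),
    )


def screen_table(
    table: TaxonTable,
    amendment: str,
    soil: str,
    alpha: float = 0.05,
    top_n: int | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Screen every genus of one treatment for ¹³C assimilation.

    Compares the three labeled heavy-fraction samples against the three
    unlabeled ones for (``amendment``, ``soil``).  ``top_n`` restricts the
    screen to the most abundant genera of the labeled treatment (rank filter
    on mean relative abundance).  ``fdr=True`` applies Benjamini–Hochberg to
    the p-values (off by default: the conventional screen is per-genus).
    """
    rel = relative_abundance(table)
    lab = table.samples_for(amendment, "C13", soil)
    unl = table.samples_for(amendment, "C12", soil)
    if len(lab) < 2 or len(unl) < 2:
        raise ValueError(
            f"need >=2 labeled and unlabeled samples for {amendment}/{soil}"
        )
    genera = list(rel.columns)
    if top_n is not None:
        ranked = rel.loc[lab].mean().sort_values(ascending=False)
        genera = list(ranked.index[:top_n])
    rows = []
    for genus in genera:
        res = assimilator_screen(
            rel.loc[lab, genus].values, rel.loc[unl, genus].values,
            alpha=alpha, genus=genus,
        )
        rows.append({
            "genus": genus,
            "mean_rel_labeled": res.mean_rel_labeled,
            "mean_rel_unlabeled": res.mean_rel_unlabeled,
            "p_value": res.p_value,
            "assimilator": res.assimilator,
        })
    out = pd.DataFrame(rows).set_index("genus")
    if fdr:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(
            out["p_value"].values, alpha=alpha, method="fdr_bh"
        )
        out["p_adjusted"] = p_adj
        out["assimilator"] = reject & (
            out["mean_rel_labeled"] > out["mean_rel_unlabeled"]
        )
    return out


def net_change(mean_treatment: float, mean_control: float) -> float:
    """Net proportional change: treatment minus control relative abundance,
    in percentage points.  Negative values mean depletion."""
    for name, v in (("mean_treatment", mean_treatment),
                    ("mean_control", mean_control)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be a percentage in [0, 100]: {v}")
    return mean_treatment - mean_control


def fold_change(
    mean_treatment: float,
    mean_control: float,
    pseudo_count: float | None = None,
) -> float:
    """Ratio of treatment to control relative abundance.

    A zero control mean makes the ratio undefined; if ``pseudo_count`` is
    given it replaces the zero denominator (callers typically use half the
    minimum nonzero relative abundance in the table and flag the output),
    otherwise :class:`UndefinedRatioError` is raised.
    """
    if mean_treatment < 0 or mean_control < 0:
        raise ValueError("relative abundances cannot be negative")
    if mean_control == 0:
        if pseudo_count is None or pseudo_count <= 0:
            raise UndefinedRatioError(
                "fold change undefined with zero control abundance "
                "(supply a pseudo_count to regularize)"
            )
        mean_control = pseudo_count
    return mean_treatment / mean_control


def half_min_nonzero(rel: pd.DataFrame) -> float:
    """Pseudo-count: half the smallest nonzero relative abundance observed."""
    vals = rel.values
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        raise UndefinedRatioError("table has no nonzero abundances")
    return float(nonzero.min()) / 2.0


def treatment_effects(
    table: TaxonTable,
    soil: str,
    isotope: str = "C13",
    amendments: tuple[str, ...] = ("FER", "GOE"),
    control: str = "CTR",
) -> pd.DataFrame:
    """Net proportional change and fold change of each genus vs the control.

    Means are taken over the (typically three) heavy-fraction samples of each
    treatment, matching the unit of replication of the screen.  Zero-control
    fold changes fall back to the half-minimum pseudo-count and are flagged
    in the ``fold_change_<amd>_pseudo`` column.
    """
    rel = relative_abundance(table)
    ctrl_samples = table.samples_for(control, isotope, soil)
    if not ctrl_samples:
        raise ValueError(f"no control samples for {control}/{soil}/{isotope}")
    ctrl_mean = rel.loc[ctrl_samples].mean()
    pseudo = half_min_nonzero(rel)
    out = pd.DataFrame({"mean_rel_ctr": ctrl_mean})
    for amd in amendments:
        samples = table.samples_for(amd, isotope, soil)
        if not samples:
            continue
        amd_mean = rel.loc[samples].mean()
        key = amd.lower()
        out[f"mean_rel_{key}"] = amd_mean
        out[f"net_change_{key}"] = [
            net_change(t, c) for t, c in zip(amd_mean, ctrl_mean)
        ]
        out[f"fold_change_{key}"] = [
            fold_change(t, c, pseudo_count=pseudo)
            for t, c in zip(amd_mean, ctrl_mean)
        ]
        out[f"fold_change_{key}_pseudo"] = ctrl_mean == 0
    return out


def filter_iron_reducers(
    table: TaxonTable, ref: IronReducerReference | None = None
) -> TaxonTable:
    """Restrict a taxon table to putative dissimilatory iron reducers.

    Column intersection with the reference genus list; counts are untouched.
    An empty intersection warns and returns an empty-genus view (a 0-column
    frame, bypassing the ≥1-genus constructor check).
    """
    if ref is None:
        ref = IronReducerReference()
    keep = [g for g in table.genera if g in ref.genera]
    if not keep:
        warnings.warn("no reference iron-reducer genera found in table",
                      stacklevel=2)
        empty = TaxonTable.__new__(TaxonTable)
        empty.counts = table.counts.iloc[:, :0]
        empty.metadata = table.metadata
        return empty
    return TaxonTable(table.counts[keep], table.metadata)
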