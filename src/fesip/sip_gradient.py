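"""Isopycnic density-gradient analysis of rRNA for stable isotope probing.

After ultracentrifugation in a cesium trifluoroacetate gradient, rRNA from
organisms that assimilated a ¹³C substrate equilibrates at a higher buoyant
density (BD) than unlabeled rRNA.  Gradients are fractionated and each
fraction's rRNA quantified by RT-qPCR; within one treatment the fraction
profile is normalized to its maximum, unlabeled rRNA bands "light"
(≈ 1.782 g ml⁻¹) and labeled rRNA "heavy" (≈ 1.791–1.806 g ml⁻¹).

Labeling is called by comparing the share of rRNA mass in the heavy window
between a ¹³C-fed gradient and its parallel ¹²C control; the fractions
carrying the labeled signal are then selected for downstream sequencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from fesip.errors import DegenerateProfileError, PairingError

#: Plausible CsTFA buoyant-density range, g ml⁻¹; values outside only warn.
CSTFA_BD_RANGE = (1.74, 1.85)


@dataclass(frozen=True)
class DensityWindows:
    """Buoyant-density windows (g ml⁻¹) for fraction classification.

    ``light_center`` ± ``light_halfwidth`` is the unlabeled band;
    [``heavy_lo``, ``heavy_hi``] is the labeled band used for shift
    detection; [``select_lo``, ``select_hi``] is the narrower window whose
    fractions are pooled for sequencing.
    """

    light_center: float = 1.782
    light_halfwidth: float = 0.004
    heavy_lo: float = 1.791
    heavy_hi: float = 1.806
    select_lo: float = 1.791
    select_hi: float = 1.801

    def __post_init__(self):
        if not (self.light_center < self.heavy_lo <= self.select_lo
                < self.select_hi <= self.heavy_hi):
            raise ValueError(
                "window ordering violated: require light_center < heavy_lo "
                "<= select_lo < select_hi <= heavy_hi"
            )
        if self.light_halfwidth <= 0:
            raise ValueError("light_halfwidth must be positive")


@dataclass
class GradientProfile:
    """Density-resolved rRNA quantification for one domain in one treatment.

    ``fraction_index`` follows the fractionation order; ``bd`` must be
    strictly monotone along it.  ``copies`` are rRNA copies per unit volume
    (or the dimensionless normalized ratio after :func:`normalize_profile`).
    """

    treatment: str
    domain: str  # "Bacteria" | "Archaea"
    fraction_index: np.ndarray
    bd: np.ndarray
    copies: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.fraction_index = np.asarray(self.fraction_index, dtype=int)
        self.bd = np.asarray(self.bd, dtype=float)
        self.copies = np.asarray(self.copies, dtype=float)
        if self.domain not in ("Bacteria", "Archaea"):
            raise ValueError(f"domain must be Bacteria or Archaea: {self.domain!r}")
        if not (len(self.fraction_index) == len(self.bd) == len(self.copies)):
            raise ValueError("fraction_index, bd and copies must be equal length")
        if len(self.bd) < 4:
            raise ValueError("a gradient profile needs at least 4 fractions")
        diffs = np.diff(self.bd)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("buoyant density must be strictly monotone")
        if np.any(self.copies < 0):
            raise ValueError("copies must be non-negative")

    def sorted_by_bd(self) -> "GradientProfile":
        order = np.argsort(self.bd)
        return replace(
            self,
            fraction_index=self.fraction_index[order],
            bd=self.bd[order],
            copies=self.copies[order],
        )


@dataclass(frozen=True)
class LabelingEvidence:
    """Outcome of a labeled-vs-unlabeled gradient comparison."""

    per_fraction_difference: np.ndarray  # normalized labeled − unlabeled, paired grid
    paired_bd: np.ndarray
    heavy_mass_fraction_labeled: float
    heavy_mass_fraction_unlabeled: float
    difference: float
    threshold: float
    shifted: bool


def normalize_profile(profile: GradientProfile) -> GradientProfile:
    """Scale a profile so its maximum fraction equals 1.

    This is the conventional within-treatment display normalization: each
    fraction's copy number divided by the treatment maximum.  Idempotent and
    invariant to overall scale.
    """
    peak = float(np.max(profile.copies))
    if peak <= 0:
        raise DegenerateProfileError(
            f"profile {profile.treatment}/{profile.domain} has no signal"
        )
    return replace(profile, copies=profile.copies / peak, normalized=True)


def classify_fraction(bd: float, windows: DensityWindows | None = None) -> str:
    """Classify a buoyant density as ``'light'``, ``'heavy'`` or ``'other'``."""
    if windows is None:
        windows = DensityWindows()
    if not CSTFA_BD_RANGE[0] <= bd <= CSTFA_BD_RANGE[1]:
        warnings.warn(
            f"buoyant density {bd} g/ml outside plausible CsTFA range "
            f"{CSTFA_BD_RANGE}", stacklevel=2,
        )
    if windows.heavy_lo <= bd <= windows.heavy_hi:
        return "heavy"
    if abs(bd - windows.light_center) <= windows.light_halfwidth:
        return "light"
    return "other"


def heavy_mass_fraction(
    profile: GradientProfile, windows: DensityWindows | None = None
) -> float:
    """Share of a profile's total rRNA signal lying in the heavy window."""
    if windows is None:
        windows = DensityWindows()
    total = float(np.sum(profile.copies))
    if total <= 0:
        raise DegenerateProfileError("cannot take mass fraction of empty profile")
    mask = (profile.bd >= windows.heavy_lo) & (profile.bd <= windows.heavy_hi)
    return float(np.sum(profile.copies[mask])) / total


def _pair_by_bd(
    a: GradientProfile, b: GradientProfile, tolerance: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match fractions of two gradients by nearest buoyant density.

    Measured BDs differ slightly between centrifuge runs, so pairing by
    fraction index is unreliable; nearest-BD matching within ``tolerance``
    is used instead.  Returns (paired bd, a copies, b copies).
    """
    a = a.sorted_by_bd()
    b = b.sorted_by_bd()
    lo = max(a.bd.min(), b.bd.min()) - tolerance
    hi = min(a.bd.max(), b.bd.max()) + tolerance
    if lo > hi:
        raise PairingError(
            f"gradients do not overlap in buoyant density: "
            f"[{a.bd.min():.4f}, {a.bd.max():.4f}] vs "
            f"[{b.bd.min():.4f}, {b.bd.max():.4f}]"
        )
    paired_bd, a_copies, b_copies = [], [], []
    for bd_val, copies_val in zip(a.bd, a.copies):
        j = int(np.argmin(np.abs(b.bd - bd_val)))
        if abs(b.bd[j] - bd_val) <= tolerance:
            paired_bd.append(0.5 * (bd_val + b.bd[j]))
            a_copies.append(copies_val)
            b_copies.append(b.copies[j])
    if not paired_bd:
        raise PairingError(
            f"no fraction pairs within tolerance {tolerance} g/ml"
        )
    return (np.asarray(paired_bd), np.asarray(a_copies), np.asarray(b_copies))


def labeling_evidence(
    labeled: GradientProfile,
    unlabeled: GradientProfile,
    windows: DensityWindows | None = None,
    threshold: float = 0.15,
    pairing_tolerance: float = 0.003,
) -> LabelingEvidence:
    """Detect a ¹³C-driven shift of rRNA into the heavy BD window.

    Both profiles are normalized (to their own maxima) if not already.  The
    statistic is the difference in heavy-window mass fraction, labeled minus
    unlabeled; a shift is called when it exceeds ``threshold``.  The
    per-fraction difference vector (on the nearest-BD paired grid) is
    returned for plotting and inspection.
    """
    if windows is None:
        windows = DensityWindows()
    if not labeled.normalized:
        labeled = normalize_profile(labeled)
    if not unlabeled.normalized:
        unlabeled = normalize_profile(unlabeled)
    paired_bd, lab_c, unl_c = _pair_by_bd(labeled, unlabeled, pairing_tolerance)
    hm_lab = heavy_mass_fraction(labeled, windows)
    hm_unl = heavy_mass_fraction(unlabeled, windows)
    diff = hm_lab - hm_unl
    return LabelingEvidence(
        per_fraction_difference=lab_c - unl_c,
        paired_bd=paired_bd,
        heavy_mass_fraction_labeled=hm_lab,
        heavy_mass_fraction_unlabeled=hm_unl,
        difference=diff,
        threshold=threshold,
        shifted=bool(diff > threshold),
    )


def select_heavy_fractions(
    profile: GradientProfile, windows: DensityWindows | None = None
) -> list[int]:
    """Indices of fractions inside the sequencing selection window.

    Selection depends only on buoyant density, never on fraction numbering;
    indices are returned in gradient order.  An empty selection warns and
    returns ``[]``.
    """
    if windows is None:
        windows = DensityWindows()
    mask = (profile.bd >= windows.select_lo) & (profile.bd <= windows.select_hi)
    selected = [int(i) for i in profile.fraction_index[mask]]
    if not selected:
        warnings.warn(
            f"no fractions of {profile.treatment}/{profile.domain} fall in "
            f"selection window [{windows.select_lo}, {windows.select_hi}] g/ml",
            stacklevel=2,
        )
    return selected
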