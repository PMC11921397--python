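"""Core qSIP inference chain for 13C enrichment.

The chain runs: per-taxon weighted average density (WAD) over density
groups -> bootstrap over replicate cores -> labeled-minus-unlabeled
density shift Z -> GC content from the unlabeled density -> per-nucleotide
molecular weights -> atom fraction excess of 13C (APE when expressed in
percent) -> active-taxon calls.

All reference constants live in :class:`IsotopeConstants` and are
overridable; only the natural-abundance 13C atom fraction (0.01111233)
is treated as physical.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IsotopeConstants",
    "DEFAULT_CONSTANTS",
    "BootstrapEstimate",
    "TaxonWad",
    "EnrichmentResult",
    "LabelOnlyTaxon",
    "compute_wad",
    "bootstrap_mean",
    "wad_difference",
    "gc_from_wad",
    "molecular_weight_light",
    "heavy_max_mass",
    "carbon_atoms_per_nucleotide",
    "labeled_mass",
    "atom_fraction_excess",
    "excess_from_shift",
    "forward_density_shift",
    "call_active",
    "call_active_label_only",
]


@dataclass(frozen=True)
class IsotopeConstants:
    """Reference constants of the density/GC/molecular-weight relations.

    gc_intercept/gc_slope
        Buoyant density of unlabeled DNA as a linear function of GC
        content: rho = gc_intercept + gc_slope * G.
    mw_intercept/mw_slope
        Mean per-nucleotide molecular weight of unlabeled DNA:
        M_light = mw_slope * G + mw_intercept (g/mol).
    background
        Natural atom fraction of 13C in carbon.
    mass_diff
        Mass difference between 13C and 12C (Da).
    """

    gc_intercept: float = 1.646057
    gc_slope: float = 0.083506
    mw_slope: float = 0.496
    mw_intercept: float = 307.691
    background: float = 0.01111233
    mass_diff: float = 1.003355


DEFAULT_CONSTANTS = IsotopeConstants()


@dataclass(frozen=True)
class BootstrapEstimate:
    """Bootstrap mean with a percentile confidence interval."""

    mean: float
    ci_low: float
    ci_high: float
    n_draws: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if np.isnan(self.mean):
            return
        # tolerate float rounding at the interval edges
        tol = 1e-9 * max(1.0, abs(self.mean))
        if not (self.ci_low - tol <= self.mean <= self.ci_high + tol):
            raise ValueError(
                f"inconsistent estimate: CI [{self.ci_low}, {self.ci_high}] "
                f"does not bracket mean {self.mean}"
            )


@dataclass
class TaxonWad:
    """Per-taxon, per-core weighted average density."""

    taxon_id: str
    core_id: str
    isotope: str
    wad: float
    groups_used: tuple[str, ...] = ()


class LabelOnlyTaxon(ValueError):
    """Taxon has no unlabeled (12C) data; the WAD-difference chain does
    not apply and the label-only activity rule must be used instead."""


def compute_wad(abundances, densities) -> float:
    """Weighted average density: WAD = sum_i x_i * rho_i.

    ``abundances`` are per-density-group (or per-fraction) abundances in
    any proportional unit (counts or copies/ng DNA); weights are
    x_i = y_i / sum_j y_j. Groups with zero abundance contribute nothing.
    Returns NaN when all abundances are zero (WAD undefined).
    """
    y = np.asarray(abundances, dtype=float)
    rho = np.asarray(densities, dtype=float)
    if y.shape != rho.shape:
        raise ValueError("abundances and densities must have equal length")
    if (y < 0).any():
        raise ValueError("abundances must be non-negative")
    total = y.sum()
    if total == 0:
        return float("nan")
    return float((y / total) @ rho)


def _percentile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    alpha = 100 * (1 - level) / 2
    lo, hi = np.nanpercentile(draws, [alpha, 100 - alpha])
    return float(lo), float(hi)


def bootstrap_mean(values, n_draws: int = 1000, seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   enumerate_all: bool = False) -> BootstrapEstimate:
    """Bootstrap the mean of per-replicate statistics.

    Replicates (cores) are resampled with replacement; the estimate is
    the mean of the draw means with a 2.5/97.5 percentile interval. With
    ``enumerate_all`` the n^n equally likely resamples are enumerated
    exactly instead of sampled (only sensible for small n).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("bootstrap requires at least one value")
    if vals.size < 2:
        warnings.warn("bootstrapping a single replicate: CI is degenerate",
                      stacklevel=2)
    if enumerate_all:
        if vals.size > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        means = np.array([
            np.mean(combo) for combo in itertools.product(vals, repeat=vals.size)
        ])
        lo, hi = _percentile_ci(means)
        return BootstrapEstimate(float(means.mean()), lo, hi, len(means), seed)
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_draws, vals.size))
    means = vals[idx].mean(axis=1)
    lo, hi = _percentile_ci(means)
    return BootstrapEstimate(float(means.mean()), lo, hi, n_draws, seed)


def wad_difference(labeled, unlabeled, n_draws: int = 1000,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   enumerate_all: bool = False) -> BootstrapEstimate:
    """Bootstrap the density shift Z = mean(W_LAB) - mean(W_LIGHT).

    Labeled (13C) and unlabeled (12C) replicate-core WADs are resampled
    independently within the same draw (paired draws), differenced per
    draw, and summarized with a percentile CI.
    """
    lab = np.asarray(labeled, dtype=float)
    unlab = np.asarray(unlabeled, dtype=float)
    if lab.size == 0:
        raise ValueError("no labeled replicates supplied")
    if unlab.size == 0:
        raise LabelOnlyTaxon(
            "taxon absent from the unlabeled treatment; use the label-only rule"
        )
    if enumerate_all:
        if lab.size > 6 or unlab.size > 6:
            raise ValueError("exhaustive enumeration is limited to n <= 6 per side")
        lab_means = np.array([
            np.mean(c) for c in itertools.product(lab, repeat=lab.size)
        ])
        unlab_means = np.array([
            np.mean(c) for c in itertools.product(unlab, repeat=unlab.size)
        ])
        diffs = (lab_means[:, None] - unlab_means[None, :]).ravel()
        lo, hi = _percentile_ci(diffs)
        return BootstrapEstimate(float(diffs.mean()), lo, hi, diffs.size, seed)
    if rng is None:
        rng = np.random.default_rng(seed)
    lab_idx = rng.integers(0, lab.size, size=(n_draws, lab.size))
    unlab_idx = rng.integers(0, unlab.size, size=(n_draws, unlab.size))
    diffs = lab[lab_idx].mean(axis=1) - unlab[unlab_idx].mean(axis=1)
    lo, hi = _percentile_ci(diffs)
    return BootstrapEstimate(float(diffs.mean()), lo, hi, n_draws, seed)


def gc_from_wad(w_light, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """GC content from the unlabeled WAD: G = (W_LIGHT - b) / m.

    Values outside [0, 1] are returned as-is (callers clamp for the mass
    formulas); a warning is emitted when G falls outside [-0.05, 1.05],
    which indicates a WAD outside the plausible DNA density range.
    """
    g = (np.asarray(w_light, dtype=float) - constants.gc_intercept) / constants.gc_slope
    out_of_range = (g < -0.05) | (g > 1.05)
    if np.any(out_of_range):
        warnings.warn(
            f"{int(np.sum(out_of_range))} GC estimate(s) outside [-0.05, 1.05]; "
            "clamped to [0, 1] for molecular-weight formulas",
            stacklevel=2,
        )
    return float(g) if g.ndim == 0 else g


def molecular_weight_light(g, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Mean per-nucleotide molecular weight of unlabeled DNA (g/mol)."""
    g = np.asarray(g, dtype=float)
    m = constants.mw_slope * g + constants.mw_intercept
    return float(m) if m.ndim == 0 else m


def carbon_atoms_per_nucleotide(g):
    """Carbon atoms per average nucleotide: N_C = 10 - 0.5 * G.

    dAMP, dTMP and dGMP carry 10 carbon atoms, dCMP carries 9, so a
    genome at GC fraction G averages G*(19/2) + (1-G)*10 = 10 - G/2.
    """
    g = np.asarray(g, dtype=float)
    n = 10.0 - 0.5 * g
    return float(n) if n.ndim == 0 else n


def heavy_max_mass(g, m_light, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Per-nucleotide molecular weight at full 13C substitution (g/mol).

    Full substitution replaces the natural-abundance carbon pool with
    pure 13C: the increment is N_C(G) * (1 - background) * mass_diff.
    """
    g = np.asarray(g, dtype=float)
    m = np.asarray(m_light, dtype=float) + (
        carbon_atoms_per_nucleotide(g)
        * (1.0 - constants.background)
        * constants.mass_diff
    )
    return float(m) if m.ndim == 0 else m


def labeled_mass(z, w_light, m_light):
    """Per-nucleotide molecular weight in the labeled treatment (g/mol).

    Uses the proportional mass-density relation:
    M_LAB = (Z / W_LIGHT + 1) * M_LIGHT.
    """
    m = (np.asarray(z, dtype=float) / np.asarray(w_light, dtype=float) + 1.0) * np.asarray(
        m_light, dtype=float
    )
    return float(m) if m.ndim == 0 else m


def atom_fraction_excess(m_lab, m_light, m_heavymax,
                         constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Atom fraction excess of 13C (multiply by 100 for APE in percent).

    A = (M_LAB - M_LIGHT) / (M_HEAVYMAX - M_LIGHT) * (1 - background).
    Negative values are reported, never clipped; activity calling alone
    enforces positivity.
    """
    m_lab = np.asarray(m_lab, dtype=float)
    m_light = np.asarray(m_light, dtype=float)
    m_heavymax = np.asarray(m_heavymax, dtype=float)
    a = (m_lab - m_light) / (m_heavymax - m_light) * (1.0 - constants.background)
    return float(a) if a.ndim == 0 else a


def excess_from_shift(w_light, z, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Full chain from a density shift to atom fraction excess.

    Convenience composition: GC from W_LIGHT (clamped to [0, 1] for the
    mass formulas), molecular weights, then atom fraction excess.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g_raw = gc_from_wad(w_light, constants)
    g = np.clip(g_raw, 0.0, 1.0)
    m_light = molecular_weight_light(g, constants)
    m_heavymax = heavy_max_mass(g, m_light, constants)
    m_lab = labeled_mass(z, w_light, m_light)
    return atom_fraction_excess(m_lab, m_light, m_heavymax, constants)


def forward_density_shift(w_light, atom_fraction,
                          constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Predict the labeled WAD of DNA at a given total 13C atom fraction.

    Exact inverse of the enrichment chain: the atom fraction excess is
    ``atom_fraction - background``; the labeled molecular weight follows
    from the full-substitution ceiling and the labeled WAD from the
    proportional mass-density relation. Round-tripping through
    :func:`excess_from_shift` recovers the excess to machine precision.
    """
    w_light = np.asarray(w_light, dtype=float)
    af = np.asarray(atom_fraction, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        g = np.clip(gc_from_wad(w_light, constants), 0.0, 1.0)
    m_light = molecular_weight_light(g, constants)
    m_heavymax = heavy_max_mass(g, m_light, constants)
    excess = af - constants.background
    m_lab = m_light + excess / (1.0 - constants.background) * (m_heavymax - m_light)
    w_lab = w_light * (m_lab / m_light)
    return float(w_lab) if w_lab.ndim == 0 else w_lab


def call_active(ape: BootstrapEstimate) -> bool:
    """CI rule: active iff the mean APE is positive and the lower 95%
    bootstrap confidence bound is above zero."""
    return bool(ape.mean > 0 and ape.ci_low > 0)


def call_active_label_only(taxon_wad: BootstrapEstimate,
                           treatment_wad: BootstrapEstimate,
                           has_unlabeled_data: bool = False) -> bool:
    """Label-only rule for taxa never detected in 12C cores.

    Active iff the lower 95% CI of the taxon's bootstrapped WAD across
    labeled cores exceeds the upper 95% CI of the community-average WAD
    of the 13C treatment. Taxa with any 12C data must use the CI rule.
    """
    if has_unlabeled_data:
        raise ValueError(
            "taxon has unlabeled (12C) data; the CI rule applies, not the "
            "label-only rule"
        )
    return bool(taxon_wad.ci_low > treatment_wad.ci_high)


@dataclass
class EnrichmentResult:
    """Per-taxon enrichment record produced by the qSIP chain."""

    taxon_id: str
    group: str
    z: float
    gc: float
    m_light: float
    m_heavymax: float
    m_lab: float
    ape: BootstrapEstimate
    active: bool
    call_route: str  # "ci_rule", "label_only_rule" or "not_active"
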