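"""Forward simulator of qSIP gradient experiments with known truth.

Each taxon gets a GC content, hence an unlabeled buoyant density, and a
true 13C atom-fraction excess (zero for inactive taxa) that shifts its
band via the same mass-density physics the analysis inverts. DNA mass is
banded as a Gaussian in density and integrated over density bins —
either the three pooled light/medium/heavy groups of the study design or
a finer per-fraction grid — then sequenced multinomially and paired with
noisy per-sample qPCR totals. Ground truth is always returned alongside
the data so recovery tests never reverse-engineer the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import DEFAULT_CONSTANTS, IsotopeConstants, forward_density_shift
from .gradient import DensityGroupScheme, FeatureTable, assign_density_group

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_experiment",
           "group_mass_fractions"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of one simulated qSIP experiment.

    Defaults emulate the study design this package targets: paired 13C/
    12C acetate treatments with 3 replicate cores each, 12 gradient
    fractions pooled into three density groups, ~50k reads per pooled
    sample, lognormal qPCR noise and occasional missing density groups.
    """

    n_taxa: int = 200
    #: soil bacterial GC content: truncated normal, mean 60 mol%
    gc_mean: float = 0.60
    gc_sd: float = 0.08
    gc_range: tuple[float, float] = (0.25, 0.78)
    #: fraction of taxa assimilating label, and their excess range
    frac_active: float = 0.5
    excess_range: tuple[float, float] = (0.01, 0.10)
    #: Gaussian banding width of a taxon's DNA in the gradient (g/mL)
    banding_sd: float = 0.005
    n_cores_labeled: int = 3
    n_cores_unlabeled: int = 3
    depth: int = 50_000
    #: mean 16S copies per ng DNA across samples, lognormal CV
    qpcr_mean: float = 2.0e5
    qpcr_cv: float = 0.20
    #: probability that a pooled density group is lost (failed sample)
    dropout_p: float = 0.05
    #: lognormal sigma of mean relative abundances across taxa
    abundance_sigma: float = 1.0
    treatments: tuple[tuple[str, str], ...] = (("natural", "anoxic"),)
    scheme: DensityGroupScheme = field(default_factory=DensityGroupScheme)
    #: pool fractions into the 3 density groups (the study design); when
    #: False, emit ``n_fractions`` uniform fractions across the gradient
    collapse: bool = True
    n_fractions: int = 30
    #: draw multinomial read counts; when False emit expected (noise-free)
    #: counts so the pipeline can be checked for exact identities
    multinomial: bool = True
    seed: int = 0
    constants: IsotopeConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p <= 1 or not 0 <= self.frac_active <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.depth <= 0 or self.n_taxa <= 0:
            raise ValueError("depth and n_taxa must be positive")
        if self.banding_sd <= 0:
            raise ValueError("banding_sd must be positive")


@dataclass
class SimulationTruth:
    """Per-taxon generative truth for recovery tests.

    ``frame`` is indexed by taxon id with columns gc, w_light,
    mean_rel_abundance and, per treatment group, ``excess_<group>``
    (true atom fraction excess), ``w_lab_<group>`` and ``active_<group>``.
    """

    frame: pd.DataFrame

    def excess(self, group: str) -> pd.Series:
        return self.frame[f"excess_{group}"]

    def active(self, group: str) -> pd.Series:
        return self.frame[f"active_{group}"]

    def to_csv(self, path) -> None:
        self.frame.rename_axis("taxon_id").to_csv(path)


def _bin_mass(center: np.ndarray, sd: float, edges: np.ndarray) -> np.ndarray:
    """Gaussian CDF mass per bin, renormalized over the full bin range.

    Returns an array (n_taxa, n_bins); rows sum to 1.
    """
    c = np.asarray(center, dtype=float)[:, None]
    cdf = stats.norm.cdf(edges[None, :], loc=c, scale=sd)
    mass = np.diff(cdf, axis=1)
    total = mass.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("a taxon bands entirely outside the density scheme")
    return mass / total


def group_mass_fractions(wad: float, sd: float,
                         scheme: DensityGroupScheme | None = None
                         ) -> dict[str, float]:
    """Share of a taxon's DNA in each density group.

    Integrates a Gaussian band (mean ``wad``, width ``sd``) over the
    group bins and renormalizes over the scheme's span, so the
    proportions sum to 1.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    scheme = scheme or DensityGroupScheme()
    mass = _bin_mass(np.array([wad]), sd, scheme.edges())[0]
    return dict(zip(scheme.names, mass))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def simulate_experiment(config: SimulationConfig, seed: int | None = None):
    """Simulate one qSIP experiment.

    Returns ``(counts, metadata, qpcr, truth)``: a read-count
    :class:`FeatureTable` whose samples are density groups (or
    fractions) of individual cores, the matching sample metadata, a
    ``{sample_id: copies_per_ng_dna}`` qPCR mapping, and the
    :class:`SimulationTruth`. Fully reproducible for a fixed config and
    seed (``seed`` overrides ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    consts = config.constants

    # --- taxa ------------------------------------------------------------
    lo, hi = config.gc_range
    a, b = (lo - config.gc_mean) / config.gc_sd, (hi - config.gc_mean) / config.gc_sd
    gc = stats.truncnorm.rvs(a, b, loc=config.gc_mean, scale=config.gc_sd,
                             size=config.n_taxa, random_state=rng)
    w_light = consts.gc_intercept + consts.gc_slope * gc
    rel = rng.lognormal(0.0, config.abundance_sigma, size=config.n_taxa)
    rel = rel / rel.sum()
    taxon_ids = [f"ASV{i + 1:04d}" for i in range(config.n_taxa)]

    truth = pd.DataFrame({"gc": gc, "w_light": w_light,
                          "mean_rel_abundance": rel}, index=taxon_ids)

    # --- density bins -----------------------------------------------------
    span_lo, span_hi = config.scheme.span
    if config.collapse:
        edges = config.scheme.edges()
        bin_labels = list(config.scheme.names)
        bin_density = [config.scheme.midpoints()[n] for n in bin_labels]
        bin_group = bin_labels
        fraction_index = [None] * len(bin_labels)
    else:
        edges = np.linspace(span_lo, span_hi, config.n_fractions + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        bin_labels = [f"f{i + 1:02d}" for i in range(config.n_fractions)]
        bin_density = list(mids)
        bin_group = [assign_density_group(m, config.scheme) for m in mids]
        fraction_index = list(range(1, config.n_fractions + 1))
    n_bins = len(bin_labels)

    # --- per-treatment truth ---------------------------------------------
    group_keys = []
    for wetland, redox in config.treatments:
        gkey = f"{wetland}_{redox}"
        group_keys.append((wetland, redox, gkey))
        active = rng.random(config.n_taxa) < config.frac_active
        excess = np.where(
            active,
            rng.uniform(*config.excess_range, size=config.n_taxa),
            0.0,
        )
        truth[f"excess_{gkey}"] = excess
        truth[f"w_lab_{gkey}"] = forward_density_shift(
            w_light, consts.background + excess, consts)
        truth[f"active_{gkey}"] = active

    # --- cores and samples ------------------------------------------------
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    qpcr: dict[str, float] = {}
    for wetland, redox, gkey in group_keys:
        for isotope, n_cores in (("13C", config.n_cores_labeled),
                                 ("12C", config.n_cores_unlabeled)):
            centers = (truth[f"w_lab_{gkey}"].to_numpy()
                       if isotope == "13C" else w_light)
            mass_frac = _bin_mass(centers, config.banding_sd, edges)
            mass = rel[:, None] * mass_frac  # taxa x bins, sums to 1
            for c in range(1, n_cores + 1):
                core_id = f"{wetland[:3]}-{redox}-{isotope}-c{c}"
                keep = rng.random(n_bins) >= config.dropout_p
                while not keep.any():
                    keep = rng.random(n_bins) >= config.dropout_p
                noise = _lognormal_factor(rng, config.qpcr_cv, n_bins)
                bin_mass_total = mass.sum(axis=0)
                for g in range(n_bins):
                    if not keep[g]:
                        continue
                    sid = f"{core_id}-{bin_labels[g]}"
                    p = mass[:, g]
                    if p.sum() == 0:
                        continue
                    p = p / p.sum()
                    if config.multinomial:
                        counts = rng.multinomial(config.depth, p).astype(float)
                    else:
                        counts = p * config.depth
                    columns[sid] = counts
                    # copies/ng proportional to the group's share of the
                    # core's total 16S pool, scaled so the across-sample
                    # mean sits at qpcr_mean
                    qpcr[sid] = float(
                        config.qpcr_mean * n_bins * bin_mass_total[g] * noise[g]
                    )
                    meta_rows.append({
                        "sample_id": sid, "core_id": core_id,
                        "wetland": wetland, "redox": redox, "isotope": isotope,
                        "fraction_index": fraction_index[g],
                        "density": bin_density[g],
                        "density_group": bin_group[g],
                    })

    taxonomy = _synthetic_taxonomy(taxon_ids, rng)
    data = pd.DataFrame(columns, index=taxon_ids)
    table = FeatureTable(data, "read_count", taxonomy)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    return table, metadata, qpcr, SimulationTruth(truth)


def _synthetic_taxonomy(taxon_ids: list[str], rng: np.random.Generator
                        ) -> pd.DataFrame:
    """Invented genus/phylum labels: ~2 ASVs per genus, 6 phyla."""
    n = len(taxon_ids)
    n_genera = max(1, n // 2)
    genus_of = rng.integers(0, n_genera, size=n)
    phylum_of_genus = rng.integers(0, 6, size=n_genera)
    rows = {}
    for tid, g in zip(taxon_ids, genus_of):
        rows[tid] = ["Bacteria", f"Phylum_{phylum_of_genus[g] + 1:02d}",
                     None, None, None, f"Genus_{g + 1:03d}"]
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["domain", "phylum", "class", "order", "family", "genus"],
    )


def write_simulation(outdir, table, metadata, qpcr, truth) -> dict[str, str]:
    """Write a simulated experiment in the formats the pipeline reads."""
    from .gradient import write_feature_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.csv",
        "qpcr": outdir / "qpcr.csv",
        "truth": outdir / "truth.csv",
    }
    write_feature_table(table, paths["counts"], "tsv")
    metadata.to_csv(paths["metadata"], index=False)
    pd.DataFrame(
        {"sample_id": list(qpcr), "copies_per_ng_dna": list(qpcr.values())}
    ).to_csv(paths["qpcr"], index=False)
    truth.to_csv(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
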