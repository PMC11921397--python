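"""qSIP model and results objects.

:class:`QsipModel` binds an absolute-abundance feature table to its
sample metadata (core, isotope, treatment group, density) and
:meth:`QsipModel.fit` runs the enrichment chain per treatment group:
per-core taxon WADs, a core-level bootstrap of the labeled-minus-
unlabeled density shift, the GC/molecular-weight conversion to 13C atom
fraction excess, and the two activity rules. :class:`QsipResults` holds
the per-taxon table, the seeds, and summary/export helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import enrichment as enr
from .enrichment import BootstrapEstimate, IsotopeConstants, DEFAULT_CONSTANTS
from .gradient import DataError, FeatureTable
from .preprocess import preprocess_counts

__all__ = ["QsipModel", "QsipResults"]

RESULT_COLUMNS = [
    "taxon", "group", "n_labeled", "n_unlabeled", "W_LIGHT", "W_LAB", "Z",
    "G", "G_raw", "M_LIGHT", "M_LAB", "M_HEAVYMAX", "APE_mean", "APE_CI_low",
    "APE_CI_high", "active", "call_route", "n_draws", "seed",
]


class QsipModel:
    """Quantitative SIP enrichment model for one experiment.

    Parameters
    ----------
    table
        Feature table in ``copies_per_ng_dna`` (preferred) or
        ``read_count`` units; samples are density groups (or fractions)
        of individual cores.
    metadata
        DataFrame indexed by sample id with columns ``core_id``,
        ``isotope`` (``12C``/``13C``), ``density`` (g/mL) and, unless
        ``group_cols`` says otherwise, ``wetland`` and ``redox`` defining
        the treatment groups compared within.
    n_draws
        Bootstrap draws (default 1000).
    constants
        Reference constants of the density/GC/mass relations.
    """

    def __init__(self, table: FeatureTable, metadata: pd.DataFrame,
                 n_draws: int = 1000,
                 group_cols: tuple[str, ...] = ("wetland", "redox"),
                 constants: IsotopeConstants = DEFAULT_CONSTANTS):
        if table.unit == "relative_abundance":
            raise ValueError(
                "per-group relative abundances cannot weight a WAD across "
                "groups; supply counts or QSEQ-normalized abundances"
            )
        md = metadata.copy()
        if "sample_id" in md.columns and md.index.name != "sample_id":
            md = md.set_index("sample_id", drop=False)
        missing = [s for s in table.sample_ids if s not in md.index]
        if missing:
            raise DataError(f"metadata lacks rows for sample(s): {missing[:5]}")
        for col in ("core_id", "isotope", "density"):
            if col not in md.columns:
                raise DataError(f"metadata is missing required column {col!r}")
        group_cols = tuple(c for c in group_cols if c in md.columns)
        self.table = table
        self.metadata = md.loc[table.sample_ids]
        self.group_cols = group_cols
        self.n_draws = int(n_draws)
        self.constants = constants

    @classmethod
    def from_counts(cls, counts: FeatureTable, metadata: pd.DataFrame, qpcr,
                    depth_k: float = 2.0, min_count: int = 3,
                    min_prevalence: float = 0.02, **kwargs) -> "QsipModel":
        """Build a model from raw counts by running the preprocessing
        chain (depth filter, rare-taxon filter, relative abundance, QSEQ)."""
        absolute, report = preprocess_counts(
            counts, qpcr, depth_k=depth_k, min_count=min_count,
            min_prevalence=min_prevalence,
        )
        model = cls(absolute, metadata.loc[[s for s in absolute.sample_ids]], **kwargs)
        model.filter_report = report
        return model

    # -- internals ---------------------------------------------------------

    def _group_key(self, row) -> str:
        if not self.group_cols:
            return "all"
        return "_".join(str(row[c]) for c in self.group_cols)

    def _core_wads(self, sample_ids) -> tuple[np.ndarray, list[str], list[list[str]]]:
        """Per-taxon WAD matrix (taxa x cores) over the given samples.

        Returns the matrix (NaN where a taxon is absent from a core),
        the core ids, and per-core lists of density groups present.
        """
        md = self.metadata.loc[list(sample_ids)]
        cores = sorted(md["core_id"].unique())
        values = self.table.data[list(sample_ids)].to_numpy(dtype=float)
        n_taxa = values.shape[0]
        wads = np.full((n_taxa, len(cores)), np.nan)
        groups_present: list[list[str]] = []
        for j, core in enumerate(cores):
            cols = [i for i, s in enumerate(sample_ids)
                    if md.loc[s, "core_id"] == core]
            y = values[:, cols]
            rho = md.iloc[cols]["density"].to_numpy(dtype=float)
            totals = y.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                w = (y @ rho) / totals
            wads[:, j] = np.where(totals > 0, w, np.nan)
            if "density_group" in md.columns:
                groups_present.append(sorted(md.iloc[cols]["density_group"].unique()))
            else:
                groups_present.append([])
        return wads, cores, groups_present

    def _community_wads(self, sample_ids) -> np.ndarray:
        """Per-core community WAD (all taxa pooled) over the samples."""
        md = self.metadata.loc[list(sample_ids)]
        cores = sorted(md["core_id"].unique())
        out = np.full(len(cores), np.nan)
        col_totals = self.table.data[list(sample_ids)].sum(axis=0).to_numpy(dtype=float)
        rho = md["density"].to_numpy(dtype=float)
        for j, core in enumerate(cores):
            sel = (md["core_id"] == core).to_numpy()
            tot = col_totals[sel].sum()
            if tot > 0:
                out[j] = (col_totals[sel] @ rho[sel]) / tot
        return out

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int | None = 0, n_draws: int | None = None) -> "QsipResults":
        """Run the enrichment chain and return per-taxon results.

        One independent bootstrap (``n_draws`` core resamples, labeled
        and unlabeled resampled within the same draw) is run per
        treatment group; all randomness derives from ``seed``.
        """
        n_draws = int(n_draws or self.n_draws)
        rng = np.random.default_rng(seed)
        md = self.metadata
        taxa = np.array(self.table.taxon_ids)
        rows: list[dict] = []
        group_keys = sorted({self._group_key(md.loc[s]) for s in self.table.sample_ids})
        groups_used: dict[tuple[str, str], tuple[str, ...]] = {}

        for gkey in group_keys:
            in_group = [s for s in self.table.sample_ids
                        if self._group_key(md.loc[s]) == gkey]
            lab_samples = [s for s in in_group if md.loc[s, "isotope"] == "13C"]
            unlab_samples = [s for s in in_group if md.loc[s, "isotope"] == "12C"]
            if not lab_samples or not unlab_samples:
                warnings.warn(
                    f"group {gkey!r} lacks a 13C or 12C treatment; skipped",
                    stacklevel=2,
                )
                continue
            w_lab, lab_cores, lab_groups = self._core_wads(lab_samples)
            w_unlab, unlab_cores, _ = self._core_wads(unlab_samples)
            n_lab_obs = (~np.isnan(w_lab)).sum(axis=1)
            n_unlab_obs = (~np.isnan(w_unlab)).sum(axis=1)
            tested = (n_lab_obs > 0) & (n_unlab_obs > 0)
            label_only = (n_lab_obs > 0) & (n_unlab_obs == 0)

            # core-level bootstrap, shared across taxa within the group
            lab_idx = rng.integers(0, len(lab_cores), size=(n_draws, len(lab_cores)))
            unlab_idx = rng.integers(0, len(unlab_cores),
                                     size=(n_draws, len(unlab_cores)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                wl_draws = np.nanmean(w_unlab[:, unlab_idx], axis=2)  # taxa x draws
                wlab_draws = np.nanmean(w_lab[:, lab_idx], axis=2)
            z_draws = wlab_draws - wl_draws
            ape_draws = enr.excess_from_shift(wl_draws, z_draws, self.constants)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                w_light_pt = np.nanmean(w_unlab, axis=1)
                w_lab_pt = np.nanmean(w_lab, axis=1)
                ape_mean = np.nanmean(ape_draws, axis=1)
                ape_lo, ape_hi = np.nanpercentile(ape_draws, [2.5, 97.5], axis=1)
            z_pt = w_lab_pt - w_light_pt
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g_raw = enr.gc_from_wad(w_light_pt, self.constants)
            g = np.clip(g_raw, 0.0, 1.0)
            m_light = enr.molecular_weight_light(g, self.constants)
            m_heavymax = enr.heavy_max_mass(g, m_light, self.constants)
            m_lab = enr.labeled_mass(z_pt, w_light_pt, m_light)

            # community WAD of the 13C treatment, for the label-only rule
            comm = self._community_wads(lab_samples)
            comm_est = enr.bootstrap_mean(comm[~np.isnan(comm)], n_draws=n_draws,
                                          rng=rng)

            for i in np.nonzero(tested)[0]:
                est = BootstrapEstimate(
                    float(ape_mean[i]), float(ape_lo[i]), float(ape_hi[i]),
                    n_draws, seed,
                )
                active = enr.call_active(est)
                rows.append({
                    "taxon": taxa[i], "group": gkey,
                    "n_labeled": int(n_lab_obs[i]),
                    "n_unlabeled": int(n_unlab_obs[i]),
                    "W_LIGHT": float(w_light_pt[i]), "W_LAB": float(w_lab_pt[i]),
                    "Z": float(z_pt[i]), "G": float(g[i]), "G_raw": float(g_raw[i]),
                    "M_LIGHT": float(m_light[i]), "M_LAB": float(m_lab[i]),
                    "M_HEAVYMAX": float(m_heavymax[i]),
                    "APE_mean": float(ape_mean[i]),
                    "APE_CI_low": float(ape_lo[i]), "APE_CI_high": float(ape_hi[i]),
                    "active": active,
                    "call_route": "ci_rule" if active else "not_active",
                    "n_draws": n_draws, "seed": seed,
                })

            for i in np.nonzero(label_only)[0]:
                vals = w_lab[i][~np.isnan(w_lab[i])]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    taxon_est = enr.bootstrap_mean(vals, n_draws=n_draws, rng=rng)
                active = enr.call_active_label_only(taxon_est, comm_est)
                rows.append({
                    "taxon": taxa[i], "group": gkey,
                    "n_labeled": int(n_lab_obs[i]), "n_unlabeled": 0,
                    "W_LIGHT": np.nan, "W_LAB": float(taxon_est.mean),
                    "Z": np.nan, "G": np.nan, "G_raw": np.nan,
                    "M_LIGHT": np.nan, "M_LAB": np.nan, "M_HEAVYMAX": np.nan,
                    "APE_mean": np.nan, "APE_CI_low": np.nan,
                    "APE_CI_high": np.nan,
                    "active": active,
                    "call_route": "label_only_rule" if active else "not_active",
                    "n_draws": n_draws, "seed": seed,
                })

            # record density groups present per core for provenance
            for core, gl in zip(lab_cores, lab_groups):
                groups_used[(gkey, core)] = tuple(gl)

        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return QsipResults(self, frame, seed=seed, n_draws=n_draws,
                           groups_used=groups_used)


@dataclass
class QsipResults:
    """Fitted qSIP results: one row per taxon per treatment group."""

    model: QsipModel
    frame: pd.DataFrame
    seed: int | None
    n_draws: int
    groups_used: dict

    @property
    def n_active(self) -> int:
        return int(self.frame["active"].sum())

    def active_taxa(self, group: str | None = None) -> list[str]:
        f = self.frame
        if group is not None:
            f = f[f["group"] == group]
        return sorted(f.loc[f["active"], "taxon"].unique())

    def active_sets(self) -> dict[str, set[str]]:
        """Active taxon ids keyed by treatment group."""
        return {
            g: set(sub.loc[sub["active"], "taxon"])
            for g, sub in self.frame.groupby("group")
        }

    def summary(self) -> str:
        """Plain-text summary of the fit, per treatment group."""
        lines = [
            "qSIP enrichment results",
            "=" * 57,
            f"bootstrap draws: {self.n_draws}    seed: {self.seed}",
            f"{'group':<28}{'tested':>7}{'label-only':>11}{'active':>8}",
            "-" * 57,
        ]
        for g, sub in self.frame.groupby("group"):
            tested = int((sub["n_unlabeled"] > 0).sum())
            lonly = int((sub["n_unlabeled"] == 0).sum())
            lines.append(f"{g:<28}{tested:>7}{lonly:>11}{int(sub['active'].sum()):>8}")
        act = self.frame.loc[self.frame["active"] & self.frame["APE_mean"].notna()]
        lines.append("-" * 57)
        if len(act):
            lines.append(
                f"mean APE of active taxa (CI rule): "
                f"{100 * act['APE_mean'].mean():.2f}%"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def plot_ape(self, group: str | None = None, ax=None):
        """Diagnostic: APE point estimates with CIs, active taxa marked."""
        import matplotlib.pyplot as plt

        f = self.frame.dropna(subset=["APE_mean"])
        if group is not None:
            f = f[f["group"] == group]
        f = f.sort_values("APE_mean").reset_index(drop=True)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        x = np.arange(len(f))
        ax.errorbar(x, 100 * f["APE_mean"],
                    yerr=[100 * (f["APE_mean"] - f["APE_CI_low"]),
                          100 * (f["APE_CI_high"] - f["APE_mean"])],
                    fmt="none", ecolor="0.7", lw=0.8)
        colors = np.where(f["active"], "tab:red", "0.4")
        ax.scatter(x, 100 * f["APE_mean"], s=8, c=colors)
        ax.axhline(0, color="k", lw=0.6)
        ax.set_xlabel("taxa (ranked)")
        ax.set_ylabel("APE (%)")
        return ax
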