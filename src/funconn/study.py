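"""Study-level orchestration: the model / results pair.

:class:`ConnectomeStudy` holds a cohort (subject records, regional time
series, optional nuisance sets) plus a :class:`~funconn.config.PipelineConfig`;
:meth:`ConnectomeStudy.fit` executes the full analysis in its fixed order —
motion screening, band-pass filtering, nuisance regression, connectivity,
sparsity thresholding, small-world metrics against degree-preserving nulls,
betweenness, targeted-attack robustness, and the 2x2 sex-by-disease
statistics — and returns a :class:`ConnectomeStudyResults` carrying every
table, with :meth:`~ConnectomeStudyResults.summary` and
:meth:`~ConnectomeStudyResults.save` for reporting and export.

All randomness (null ensembles) derives from the pipeline seed, so a rerun
with the same inputs and configuration reproduces every output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, PipelineConfig, config_hash
from .connectivity import (ConnectivityMatrix, correlation_matrix,
                           edge_group_stats, threshold_by_sparsity)
from .graph import BinaryGraph
from .metrics import (GlobalMetrics, betweenness, characteristic_path_length,
                      network_clustering, small_world_metrics)
from .preprocess import bandpass, regress_nuisance, screen_motion
from .robustness import compare_curves, group_attack_analysis
from .stats import (fdr_adjust, partial_correlation, posthoc_pairwise,
                    two_way_anova)
from .synthetic import Cohort, generate_cohort

__all__ = ["ConnectomeStudy", "ConnectomeStudyResults"]


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ConnectomeStudyResults:
    """All outputs of one fitted study."""

    config: PipelineConfig
    qc: pd.DataFrame
    subjects: pd.DataFrame
    global_metrics: pd.DataFrame          # per subject at analysis sparsity
    sweep_metrics: pd.DataFrame           # per subject x sparsity: C, L
    betweenness: pd.DataFrame             # subjects x regions
    metric_anova: pd.DataFrame            # family of global metrics
    nodal_anova: pd.DataFrame             # betweenness per region
    posthoc: dict[str, pd.DataFrame]
    robustness: dict[str, pd.DataFrame]   # per sex: grid, group means, p
    partial_corr: pd.DataFrame
    edge_stats: pd.DataFrame | None = None
    excluded_subjects: list[str] = field(default_factory=list)

    def summary(self) -> str:
        """Readable run summary in the spirit of a model results table."""
        lines = ["Connectome study results", "=" * 60]
        n = len(self.subjects)
        cells = (self.subjects.groupby(["sex", "group"]).size()
                 .rename("n").reset_index())
        lines.append(f"subjects analyzed: {n}   "
                     f"(excluded by motion QC: {len(self.excluded_subjects)})")
        for _, r in cells.iterrows():
            lines.append(f"  {r['sex']:>6} / {r['group']:<8} n={r['n']}")
        s = self.config.analysis_sparsity
        lines.append(f"analysis sparsity: {s:.2f}  "
                     f"(sweep {self.config.sparsity_low:.2f}-"
                     f"{self.config.sparsity_high:.2f})")
        lines.append("-" * 60)
        lines.append("global small-world metrics (cohort mean +/- SD):")
        for m in ("C", "L", "gamma", "lambda", "sigma"):
            v = self.global_metrics[m]
            lines.append(f"  {m:>6}: {v.mean():.4f} +/- {v.std():.4f}")
        lines.append("-" * 60)
        lines.append("two-way ANOVA (sex x disease), FDR-adjusted interaction p:")
        for _, r in self.metric_anova.iterrows():
            flag = " *" if r["interaction_significant"] else ""
            lines.append(f"  {r['metric']:>6}: F={r['F_interaction']:.2f} "
                         f"p={r['p_interaction']:.4f} "
                         f"p_fdr={r['p_interaction_fdr']:.4f}{flag}")
        n_sig = int(self.nodal_anova["interaction_significant"].sum())
        lines.append(f"regions with significant betweenness interaction "
                     f"(FDR q={self.config.fdr_q}): {n_sig}")
        for _, r in self.partial_corr.iterrows():
            lines.append(f"partial corr ({r['subset']}, {r['x']} vs {r['y']} "
                         f"| age): r={r['r_partial']:.3f} p={r['p']:.4f} "
                         f"n={int(r['n'])}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write every results table plus a run manifest to ``outdir``."""
        from . import __version__
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        head = (f"# funconn v{__version__} stage=results "
                f"config={config_hash(self.config)}\n")

        def dump(df: pd.DataFrame, name: str, index=False) -> None:
            with open(outdir / name, "w") as fh:
                fh.write(head)
                df.to_csv(fh, index=index, float_format="%.8g",
                          lineterminator="\n")

        dump(self.qc, "qc.csv")
        dump(self.subjects, "subjects.csv")
        dump(self.global_metrics, "global_metrics.csv")
        dump(self.sweep_metrics, "sweep_metrics.csv")
        dump(self.betweenness, "betweenness.csv", index=True)
        dump(self.metric_anova, "metric_anova.csv")
        dump(self.nodal_anova, "nodal_anova.csv")
        dump(self.partial_corr, "partial_correlations.csv")
        for sex, df in self.robustness.items():
            dump(df, f"robustness_{sex}.tsv")
        for metric, df in self.posthoc.items():
            dump(df, f"posthoc_{metric}.csv")
        if self.edge_stats is not None:
            dump(self.edge_stats, "edge_stats.csv")
        manifest = {
            "funconn_version": __version__,
            "config": self.config.to_dict(),
            "config_hash": config_hash(self.config),
            "n_subjects": int(len(self.subjects)),
            "excluded_subjects": list(self.excluded_subjects),
            "files": sorted(p.name for p in outdir.iterdir()),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")


class ConnectomeStudy:
    """A cohort plus analysis configuration, ready to fit.

    Parameters
    ----------
    subjects
        List of :class:`~funconn.synthetic.SubjectRecord`.
    timeseries
        Mapping subject_id -> :class:`~funconn.synthetic.RoiTimeSeries`.
    nuisance
        Optional mapping subject_id -> :class:`~funconn.synthetic.NuisanceSet`;
        subjects without nuisance skip motion QC and nuisance regression.
    config
        :class:`~funconn.config.PipelineConfig`; defaults follow the study
        design (band 0.01-0.08 Hz, sweep 0.15-0.25, S = 0.15, q = 0.05).
    """

    def __init__(self, subjects, timeseries, nuisance=None,
                 config: PipelineConfig | None = None):
        self.subjects = list(subjects)
        self.timeseries = dict(timeseries)
        self.nuisance = dict(nuisance or {})
        self.config = config or PipelineConfig()
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        missing = [i for i in ids if i not in self.timeseries]
        if missing:
            raise ValueError(f"missing time series for subjects {missing[:5]}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def simulate(cls, cohort_config: CohortConfig | None = None,
                 config: PipelineConfig | None = None) -> "ConnectomeStudy":
        """Generate a synthetic cohort and wrap it as a study."""
        cohort = generate_cohort(cohort_config)
        study = cls(cohort.subjects, cohort.timeseries, cohort.nuisance, config)
        study.cohort = cohort
        return study

    @classmethod
    def from_directory(cls, path,
                       config: PipelineConfig | None = None) -> "ConnectomeStudy":
        """Build a study from an on-disk cohort directory."""
        from .io import load_cohort

        subjects, timeseries, nuisance = load_cohort(path)
        return cls(subjects, timeseries, nuisance, config)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> ConnectomeStudyResults:
        cfg = self.config
        qc_rows, keep, excluded = [], [], []
        for s in self.subjects:
            if s.subject_id in self.nuisance:
                passed, summary = screen_motion(
                    self.nuisance[s.subject_id],
                    cfg.displacement_limit_mm, cfg.rotation_limit_deg)
                qc_rows.append({
                    "subject_id": s.subject_id,
                    "max_displacement_mm": summary.worst_displacement,
                    "max_rotation_deg": summary.worst_rotation,
                    "passed": passed,
                })
            else:
                passed = True
                qc_rows.append({"subject_id": s.subject_id,
                                "max_displacement_mm": np.nan,
                                "max_rotation_deg": np.nan, "passed": True})
            (keep if passed else excluded).append(s.subject_id)
        qc = pd.DataFrame(qc_rows)
        subjects = [s for s in self.subjects if s.subject_id in set(keep)]
        if len(subjects) < 8:
            raise StageError("qc", f"only {len(subjects)} subjects pass "
                             "motion screening; need >= 8 for the 2x2 design")

        # preprocessing: band-pass first, then nuisance regression
        matrices: dict[str, ConnectivityMatrix] = {}
        for s in subjects:
            ts = self.timeseries[s.subject_id]
            try:
                ts = bandpass(ts, cfg.bandpass_low_hz, cfg.bandpass_high_hz)
                if s.subject_id in self.nuisance:
                    ts = regress_nuisance(ts, self.nuisance[s.subject_id])
                matrices[s.subject_id] = correlation_matrix(ts)
            except Exception as e:
                raise StageError("preprocess",
                                 f"subject {s.subject_id}: {e}") from e

        labels = matrices[subjects[0].subject_id].region_labels
        n_regions = len(labels)

        # graphs and metrics
        graphs: dict[str, BinaryGraph] = {}
        sweep_rows, metric_rows = [], []
        bt = np.zeros((len(subjects), n_regions))
        root = np.random.SeedSequence(cfg.seed)
        subj_seeds = root.spawn(len(subjects))
        for i, s in enumerate(subjects):
            c = matrices[s.subject_id]
            g = threshold_by_sparsity(c, cfg.analysis_sparsity,
                                      cfg.threshold_mode)
            graphs[s.subject_id] = g
            if not g.is_connected():
                raise StageError(
                    "netbuild",
                    f"subject {s.subject_id}: graph disconnected at sparsity "
                    f"{cfg.analysis_sparsity}; raise analysis_sparsity (see "
                    "min_connected_sparsity)")
            seed_i = int(subj_seeds[i].generate_state(1)[0] % (2 ** 31))
            gm, _ = small_world_metrics(g, cfg.n_random, seed=seed_i,
                                        n_swaps_per_edge=cfg.swaps_per_edge)
            metric_rows.append({
                "subject_id": s.subject_id, "sex": s.sex, "group": s.group,
                "sparsity": g.sparsity, "C": gm.C, "L": gm.L,
                "C_rand": gm.C_rand, "L_rand": gm.L_rand,
                "gamma": gm.gamma, "lambda": gm.lambda_, "sigma": gm.sigma,
            })
            bt[i] = betweenness(g)
            for sp in cfg.sparsities:
                gs = threshold_by_sparsity(c, sp, cfg.threshold_mode)
                row = {"subject_id": s.subject_id, "sex": s.sex,
                       "group": s.group, "sparsity": sp,
                       "C": network_clustering(gs)}
                row["L"] = (characteristic_path_length(gs)
                            if gs.is_connected() else np.nan)
                sweep_rows.append(row)

        global_metrics = pd.DataFrame(metric_rows)
        sweep_metrics = pd.DataFrame(sweep_rows)
        bt_df = pd.DataFrame(bt, index=[s.subject_id for s in subjects],
                             columns=labels)

        sex = np.array([s.sex for s in subjects])
        group = np.array([s.group for s in subjects])

        # global-metric family ANOVA with FDR across metrics
        metric_names = ["C", "L", "gamma", "lambda", "sigma"]
        anova_rows, posthoc = [], {}
        for m in metric_names:
            res = two_way_anova(global_metrics[m].to_numpy(), sex, group,
                                metric_name=m, ss_type=cfg.ss_type)
            anova_rows.append(res.to_row())
        metric_anova = pd.DataFrame(anova_rows)
        p_adj, rej = fdr_adjust(metric_anova["p_interaction"], cfg.fdr_q,
                                cfg.fdr_method)
        metric_anova["p_interaction_fdr"] = p_adj
        metric_anova["interaction_significant"] = rej
        for m, significant in zip(metric_names, rej):
            if significant:
                posthoc[m] = posthoc_pairwise(
                    global_metrics[m].to_numpy(), sex, group, alpha=cfg.fdr_q)

        # nodal betweenness ANOVA with FDR across regions
        from .stats import anova_table_many

        nodal = anova_table_many(bt, sex, group, ss_type=cfg.ss_type)
        nodal.insert(0, "region", labels)
        p_adj, rej = fdr_adjust(nodal["p_interaction"], cfg.fdr_q,
                                cfg.fdr_method)
        nodal["p_interaction_fdr"] = p_adj
        nodal["interaction_significant"] = rej
        for cell_sex in ("female", "male"):
            for cell_group in ("patient", "control"):
                mask = (sex == cell_sex) & (group == cell_group)
                nodal[f"mean_{cell_sex}_{cell_group}"] = bt[mask].mean(axis=0)
                nodal[f"sd_{cell_sex}_{cell_group}"] = bt[mask].std(axis=0,
                                                                    ddof=1)

        # robustness: per sex, attack order pooled over that sex's subjects
        robustness = {}
        ids = [s.subject_id for s in subjects]
        for cell_sex in ("female", "male"):
            idx = np.nonzero(sex == cell_sex)[0]
            if idx.size == 0:
                continue
            sub_ids = [ids[i] for i in idx]
            curves = group_attack_analysis(
                graphs, bt[idx], sub_ids, recompute=cfg.attack_recompute)
            pat = [curves[i] for i in sub_ids
                   if group[ids.index(i)] == "patient"]
            con = [curves[i] for i in sub_ids
                   if group[ids.index(i)] == "control"]
            if len(pat) >= 2 and len(con) >= 2:
                cmp_df = compare_curves(pat, con, alpha=cfg.fdr_q)
                cmp_df = cmp_df.rename(columns={"mean_lcc_a": "mean_lcc_patient",
                                                "mean_lcc_b": "mean_lcc_control"})
            else:
                grid = curves[sub_ids[0]].removed_fraction
                cmp_df = pd.DataFrame({"removed_fraction": grid})
            robustness[cell_sex] = cmp_df

        # age-controlled partial correlations: duration vs small-worldness
        pc_rows = []
        gm_by_id = global_metrics.set_index("subject_id")
        for subset, selector in (
            ("patients", lambda s: s.group == "patient"),
            ("female_patients", lambda s: s.group == "patient" and s.sex == "female"),
            ("male_patients", lambda s: s.group == "patient" and s.sex == "male"),
        ):
            sel = [s for s in subjects
                   if selector(s) and s.disease_duration is not None]
            if len(sel) < 5:
                continue
            x = np.array([s.disease_duration for s in sel])
            y = gm_by_id.loc[[s.subject_id for s in sel], "sigma"].to_numpy()
            age = np.array([s.age for s in sel])
            res = partial_correlation(x, y, age)
            pc_rows.append({"subset": subset, "x": "disease_duration",
                            "y": "sigma", "r_partial": res.r_partial,
                            "p": res.p, "n": res.n})
        partial_corr = pd.DataFrame(
            pc_rows, columns=["subset", "x", "y", "r_partial", "p", "n"])

        edge_stats = None
        if cfg.edge_stats:
            edge_stats = edge_group_stats(
                matrices, {s.subject_id: s.group for s in subjects},
                q=cfg.fdr_q)

        subjects_df = pd.DataFrame([{
            "subject_id": s.subject_id, "sex": s.sex, "group": s.group,
            "age": s.age, "disease_duration": s.disease_duration,
            "attack_frequency": s.attack_frequency,
            "attack_duration": s.attack_duration,
            "pain_intensity": s.pain_intensity,
        } for s in subjects])

        return ConnectomeStudyResults(
            config=cfg, qc=qc, subjects=subjects_df,
            global_metrics=global_metrics, sweep_metrics=sweep_metrics,
            betweenness=bt_df, metric_anova=metric_anova, nodal_anova=nodal,
            posthoc=posthoc, robustness=robustness,
            partial_corr=partial_corr, edge_stats=edge_stats,
            excluded_subjects=excluded,
        )
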