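"""Top-level Model/Results interface for a feature-selection study.

``FeatureSelectionStudy`` holds the occurrence-level feature table (one row
per 1 s window with participant, population and activity label columns);
``fit()`` runs the three filter selectors per level and population, then
evaluates every subset against the full feature set with participant-wise
LOOCV, paired sign tests and Benjamini-Hochberg correction, returning a
``StudyResults`` with the selection grid, accuracies, comparisons and
report tables.

Typical use::

    cohort = synthetic.generate_cohort({"able_bodied": 3, "stroke": 3},
                                       script, seed=7)
    study = FeatureSelectionStudy.from_recordings(cohort)
    res = study.fit(seed=7)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, features, preprocessing, selection

META_COLUMNS = ("participant_id", "population", "window_index", "label")
POOLED = "all_populations"


def build_feature_table(cohort, span: int = 3) -> pd.DataFrame:
    """Windows -> features for a cohort of simulated participants.

    For each participant: estimate the orientation correction from the
    calibration sample, segment 1 s windows, apply the +/-2 s transition
    buffer, and compute the 76-feature matrix.  Returns one tidy table with
    meta columns (participant_id, population, window_index, label) plus
    f1..f76.
    """
    frames = []
    for part in cohort:
        correction = preprocessing.estimate_orientation_correction(part.calibration)
        windows = preprocessing.segment_windows(part.recording)
        windows = preprocessing.apply_transition_buffer(
            windows, part.recording.annotations()
        )
        fx = features.feature_matrix(windows, correction, span=span)
        fx.insert(0, "participant_id", part.participant_id)
        fx.insert(1, "population", part.profile.profile_id)
        fx.insert(2, "window_index", [w.index for w in windows])
        fx.insert(3, "label", [w.label for w in windows])
        frames.append(fx)
    return pd.concat(frames, ignore_index=True)


class FeatureSelectionStudy:
    """Feature-selection study over a labelled occurrence table.

    Parameters
    ----------
    data : DataFrame
        One row per 1 s window with columns ``participant_id``,
        ``population``, ``label`` (activity or transition label),
        optionally ``window_index``, and the feature columns f1..f76.
    levels : iterable of int
        Detail levels (1-7) to analyse.
    populations : 'auto' or list
        Population tags to analyse separately; a pooled all-populations
        family is always added when more than one population is present.
    """

    def __init__(self, data: pd.DataFrame, levels=preprocessing.LEVELS,
                 populations="auto"):
        missing = [c for c in ("participant_id", "population", "label")
                   if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks required columns: {missing}")
        self.feature_columns = [c for c in data.columns
                                if c.startswith("f") and c[1:].isdigit()]
        if not self.feature_columns:
            raise ValueError("data has no feature columns (f1..f76)")
        self.data = data.reset_index(drop=True)
        self.levels = tuple(levels)
        if populations == "auto":
            populations = sorted(self.data["population"].unique())
        self.populations = list(populations)

    @classmethod
    def from_recordings(cls, cohort, span: int = 3, **kwargs):
        return cls(build_feature_table(cohort, span=span), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(df, **kwargs)

    # -- dataset assembly ---------------------------------------------------

    def _windows_view(self, mask):
        sub = self.data[mask]
        return sub

    def level_dataset(self, level: int, population: str | None = None):
        """LevelDataset for one level, one population (None = pooled)."""
        sub = self.data
        if population is not None and population != POOLED:
            sub = sub[sub["population"] == population]
        keep, classes = [], []
        for i, lbl in zip(sub.index, sub["label"]):
            cls_ = preprocessing.map_label_to_level(str(lbl), level)
            if cls_ is not None:
                keep.append(i)
                classes.append(cls_)
        X = sub.loc[keep, self.feature_columns].reset_index(drop=True)
        widx = (sub.loc[keep, "window_index"].to_numpy()
                if "window_index" in sub.columns else np.arange(len(keep)))
        return preprocessing.LevelDataset(
            level=level,
            X=X,
            y=np.asarray(classes, dtype=object),
            groups=sub.loc[keep, "participant_id"].to_numpy(dtype=object),
            window_index=np.asarray(widx),
        )

    def level_datasets(self) -> dict:
        """(population, level) -> LevelDataset, including the pooled family."""
        fams = list(self.populations)
        if len(self.populations) > 1:
            fams.append(POOLED)
        out = {}
        for population in fams:
            for level in self.levels:
                ds = self.level_dataset(level, population)
                if ds.n_occurrences:
                    out[(population, level)] = ds
        return out

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        methods=selection.METHODS,
        classifiers=evaluation.CLASSIFIERS,
        k: int = 10,
        q: float = 0.05,
        seed: int = 0,
        selection_scope: str = "fixed",
        n_bins: int = 10,
        evaluate: bool = True,
    ) -> "StudyResults":
        """Run selection and (optionally) LOOCV evaluation.

        ``selection_scope='fixed'`` selects once on each full level dataset
        and evaluates that subset in every fold (the design the published
        tables imply); ``'per_fold'`` re-runs selection inside each training
        fold (no selection leakage).  Both modes are exposed because the
        original procedure is ambiguous on this point.
        """
        if selection_scope not in ("fixed", "per_fold"):
            raise ValueError("selection_scope must be 'fixed' or 'per_fold'")
        datasets = self.level_datasets()
        grid = selection.run_selection_grid(datasets, methods=methods, k=k)
        cv_results, comparisons = [], []
        if evaluate:
            for (population, level), ds in datasets.items():
                if len(set(ds.y)) < 2 or len(set(ds.groups)) < 2:
                    continue
                sel_rows = grid[(grid["population"] == population)
                                & (grid["level"] == level)]
                for clf in classifiers:
                    base = evaluation.loocv_by_participant(ds, clf, seed=seed)
                    base.population = population
                    cv_results.append(base)
                    for _, row in sel_rows.iterrows():
                        subset = row["subset"]
                        if not subset.indices:
                            continue
                        if selection_scope == "per_fold":
                            method = row["method"]
                            sel = (lambda Xtr, ytr, m=method:
                                   selection.select(m, Xtr, ytr, k=k).indices)
                            res = evaluation.loocv_by_participant(
                                ds, clf, seed=seed, selector=sel)
                            res.feature_set = method
                        else:
                            res = evaluation.loocv_by_participant(
                                ds, clf, subset=subset, seed=seed)
                            res.feature_set = row["method"]
                        res.population = population
                        cv_results.append(res)
                        st = evaluation.paired_sign_test(
                            res.fold_accuracies, base.fold_accuracies)
                        comparisons.append(
                            {"population": population, "level": level,
                             "classifier": clf, "feature_set": res.feature_set,
                             "n_pos": st.n_pos, "n_neg": st.n_neg,
                             "n_ties": st.n_ties, "p": st.p,
                             "mean_selected": res.mean_accuracy,
                             "mean_all": base.mean_accuracy}
                        )
        comp = pd.DataFrame(comparisons)
        if len(comp):
            comp["adjusted_p"] = np.nan
            comp["significant"] = False
            # BH family: all (level x classifier x method) tests per population
            for population in comp["population"].unique():
                m = comp["population"] == population
                rej, adj = evaluation.benjamini_hochberg(comp.loc[m, "p"], q=q)
                comp.loc[m, "adjusted_p"] = adj
                comp.loc[m, "significant"] = rej
        return StudyResults(
            study=self, selection_grid=grid, cv_results=cv_results,
            comparisons=comp, config={
                "methods": tuple(methods), "classifiers": tuple(classifiers),
                "k": k, "q": q, "seed": seed,
                "selection_scope": selection_scope, "n_bins": n_bins,
            },
        )


@dataclass
class StudyResults:
    """Fitted study: selection grid, LOOCV accuracies, sign tests, reports."""

    study: FeatureSelectionStudy
    selection_grid: pd.DataFrame
    cv_results: list
    comparisons: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def accuracies_(self) -> pd.DataFrame:
        return evaluation.accuracy_table(
            self.cv_results,
            self.comparisons if len(self.comparisons) else None,
        )

    def subset(self, population: str, level: int, method: str):
        row = self.selection_grid[
            (self.selection_grid["population"] == population)
            & (self.selection_grid["level"] == level)
            & (self.selection_grid["method"] == method)
        ]
        return row.iloc[0]["subset"] if len(row) else None

    def common_features(self, method: str) -> pd.DataFrame:
        return selection.common_features(self.selection_grid, method)

    def confusions(self) -> dict:
        return {
            f"{r.population}_L{r.level}_{r.classifier}_{r.feature_set}":
                evaluation.confusion_frame(r)
            for r in self.cv_results
        }

    def summary(self) -> str:
        """Plain-text summary: selected subsets and accuracy comparisons."""
        lines = ["Feature selection study", "=" * 70]
        grid = self.selection_grid.copy()
        if len(grid):
            grid["feature_ids"] = grid["feature_ids"].map(
                lambda ids: ", ".join(str(i) for i in sorted(ids)))
            lines.append("Selected features (1-based ids) per population/level:")
            lines.append(grid[["population", "level", "method", "n_selected",
                               "feature_ids"]].to_string(index=False))
        acc = self.accuracies_
        if len(acc):
            lines.append("")
            lines.append("Mean LOOCV accuracy (%) per feature set:")
            pivot = acc.pivot_table(
                index=["population", "classifier", "feature_set"],
                columns="level", values="mean_accuracy")
            lines.append(pivot.round(2).to_string())
        if len(self.comparisons):
            sig = self.comparisons[self.comparisons["significant"]]
            lines.append("")
            lines.append(
                f"{len(sig)} of {len(self.comparisons)} subset-vs-all "
                f"comparisons significant after Benjamini-Hochberg "
                f"(q={self.config.get('q', 0.05)})."
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the report tables plus a provenance log (config hash,
        seeds, library versions)."""
        common = {
            m: self.common_features(m)
            for m in self.selection_grid["method"].unique()
        } if len(self.selection_grid) else {}
        evaluation.write_reports(outdir, self.accuracies_, self.confusions(),
                                 common)
        self._write_provenance(outdir)

    def _write_provenance(self, outdir) -> None:
        import hashlib
        import os

        import sklearn
        import yaml

        from . import __version__

        config = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in self.config.items()}
        digest = hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]
        log = {
            "config": config,
            "config_hash": digest,
            "n_occurrences": int(len(self.study.data)),
            "populations": list(self.study.populations),
            "versions": {
                "harselect": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        with open(os.path.join(outdir, "provenance.yaml"), "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=False)

    def plot_accuracy(self, population: str | None = None, ax=None):
        """Bar chart of mean accuracy per level and feature set."""
        import matplotlib.pyplot as plt

        acc = self.accuracies_
        if population is not None:
            acc = acc[acc["population"] == population]
        pivot = acc.pivot_table(index="level", columns="feature_set",
                                values="mean_accuracy")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        pivot.plot.bar(ax=ax)
        ax.set_ylabel("mean LOOCV accuracy (%)")
        ax.set_xlabel("detail level")
        ax.set_ylim(0, 100)
        return ax
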