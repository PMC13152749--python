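"""Diagnostic evaluation of a feature table, statsmodels-style.

:class:`FeatureDiagnostics` is built from a per-lesion feature table with a
binary metastasis label; ``fit()`` runs the study's evaluation — group
comparison and selection, ROC with Youden operating points, pairwise DeLong,
logistic probability calibration with the Hosmer-Lemeshow test, and decision
curves — and returns a :class:`DiagnosticsResults` carrying everything, with
``summary()`` and table/plot accessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as st

__all__ = ["FeatureDiagnostics", "DiagnosticsResults"]


class FeatureDiagnostics:
    """Single-feature diagnostic model for a lesion cohort.

    Parameters
    ----------
    table : DataFrame
        Rows are lesions; must contain ``label_col`` with values {0, 1} and
        at least one numeric feature column.
    label_col : str
        Name of the binary metastasis label column (1 = metastatic).
    features : list of str, optional
        Feature columns to evaluate; default: every non-label numeric column.
    p_max, auc_min : float
        The selection filter: keep features with p ≤ p_max and
        orientation-free AUC > auc_min.
    hl_bins : int
        Bins of the Hosmer-Lemeshow test.
    dca_thresholds : array-like
        Threshold-probability grid of the decision curves.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        label_col: str = "label",
        features: list[str] | None = None,
        p_max: float = 0.05,
        auc_min: float = 0.7,
        hl_bins: int = 10,
        dca_thresholds=None,
    ):
        if label_col not in table.columns:
            raise ValueError(f"label column {label_col!r} missing")
        y = np.asarray(table[label_col])
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("labels must be binary {0, 1}")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present for evaluation")
        if features is None:
            features = [
                c
                for c in table.columns
                if c != label_col and np.issubdtype(table[c].dtype, np.number)
            ]
        if not features:
            raise ValueError("no feature columns to evaluate")
        bad = [c for c in features if table[c].isna().any()]
        if bad:
            raise ValueError(f"missing values in features: {bad}")
        self.table = table.reset_index(drop=True)
        self.label_col = label_col
        self.features = list(features)
        self.p_max = p_max
        self.auc_min = auc_min
        self.hl_bins = hl_bins
        self.dca_thresholds = (
            np.arange(0.01, 1.0, 0.01) if dca_thresholds is None else np.asarray(dca_thresholds)
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "FeatureDiagnostics":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self) -> "DiagnosticsResults":
        y = np.asarray(self.table[self.label_col]).astype(int)
        retained, selection = st.select_features(
            self.table, self.label_col, self.features, self.p_max, self.auc_min
        )
        evaluated = retained if retained else []
        roc: dict[str, st.RocResult] = {}
        calibration: dict[str, st.CalibrationResult] = {}
        dca: dict[str, st.NetBenefitCurve] = {}
        probs: dict[str, np.ndarray] = {}
        prob_info: dict[str, dict] = {}
        for name in evaluated:
            x = np.asarray(self.table[name], dtype=float)
            # evaluate on oriented scores so higher = more likely positive;
            # the threshold is reported on the oriented scale
            if selection.loc[name, "orientation"] < 0:
                x = -x
            roc[name] = st.youden_threshold(x, y)
            pr, info = st.probability_from_feature(x, y)
            probs[name] = pr
            prob_info[name] = info
            calibration[name] = st.hosmer_lemeshow(pr, y, g=self.hl_bins)
            dca[name] = st.decision_curve(pr, y, self.dca_thresholds)
        delong = {}
        for i, a in enumerate(evaluated):
            for b in evaluated[i + 1 :]:
                xa = np.asarray(self.table[a], dtype=float)
                xb = np.asarray(self.table[b], dtype=float)
                # orient both so higher = more likely positive
                if selection.loc[a, "orientation"] < 0:
                    xa = -xa
                if selection.loc[b, "orientation"] < 0:
                    xb = -xb
                delong[(a, b)] = st.delong_test(xa, xb, y)
        return DiagnosticsResults(
            model=self,
            labels=y,
            selection=selection,
            retained=retained,
            roc=roc,
            probabilities=probs,
            probability_info=prob_info,
            calibration=calibration,
            decision_curves=dca,
            delong=delong,
        )


@dataclass
class DiagnosticsResults:
    """Fitted diagnostic evaluation; see :class:`FeatureDiagnostics`."""

    model: FeatureDiagnostics
    labels: np.ndarray
    selection: pd.DataFrame
    retained: list[str]
    roc: dict
    probabilities: dict
    probability_info: dict
    calibration: dict
    decision_curves: dict
    delong: dict

    # -- tables ------------------------------------------------------------

    def table2(self) -> pd.DataFrame:
        """Per-group median [Q1, Q3] and p-value of each retained feature."""
        rows = []
        t = self.model.table
        y = self.labels
        for name in self.retained:
            x = np.asarray(t[name], dtype=float)
            x0, x1 = x[y == 0], x[y == 1]

            def fmt(v):
                return (
                    f"{np.median(v):.2f} [{np.percentile(v, 25):.2f},"
                    f"{np.percentile(v, 75):.2f}]"
                )

            rows.append(
                {
                    "feature": name,
                    "overall": fmt(x),
                    "label0": fmt(x0),
                    "label1": fmt(x1),
                    "p_value": self.selection.loc[name, "p_value"],
                }
            )
        return pd.DataFrame(rows)

    def table3(self) -> pd.DataFrame:
        """Threshold/ACC/AUC/Se/Sp/NPV/PPV/F1 row per retained feature."""
        rows = []
        for name in self.retained:
            r = self.roc[name]
            m = r.metrics
            rows.append(
                {
                    "feature": name,
                    "threshold": r.threshold,
                    "accuracy": m["accuracy"],
                    "auc": r.auc,
                    "sensitivity": m["sensitivity"],
                    "specificity": m["specificity"],
                    "npv": m["npv"],
                    "ppv": m["ppv"],
                    "f1": m["f1"],
                }
            )
        return pd.DataFrame(rows)

    def delong_matrix(self) -> pd.DataFrame:
        names = self.retained
        out = pd.DataFrame(np.nan, index=names, columns=names)
        for (a, b), (_, _, _, p) in self.delong.items():
            out.loc[a, b] = p
            out.loc[b, a] = p
        np.fill_diagonal(out.values, 1.0)
        return out

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = []
        n1 = int(self.labels.sum())
        n0 = len(self.labels) - n1
        lines.append("Feature diagnostic evaluation")
        lines.append("=" * 64)
        lines.append(f"lesions: {len(self.labels)}  (label=0: {n0}, label=1: {n1})")
        lines.append(
            f"selection: p <= {self.model.p_max}, oriented AUC > {self.model.auc_min}"
            f" -> {len(self.retained)}/{len(self.model.features)} retained"
        )
        lines.append("")
        lines.append(
            f"{'feature':<38}{'p':>9}{'AUC':>7}{'thr':>12}{'ACC':>7}"
            f"{'Se':>7}{'Sp':>7}{'F1':>7}{'HL p':>7}"
        )
        lines.append("-" * 101)
        for name in self.retained:
            r = self.roc[name]
            m = r.metrics
            hl = self.calibration[name]
            p = self.selection.loc[name, "p_value"]
            p_str = "<0.001" if p < 0.001 else f"{p:.3f}"
            lines.append(
                f"{name:<38}{p_str:>9}{r.auc:>7.3f}{r.threshold:>12.4g}"
                f"{m['accuracy']:>7.3f}{m['sensitivity']:>7.3f}"
                f"{m['specificity']:>7.3f}{m['f1']:>7.3f}{hl.p_value:>7.3f}"
            )
        dropped = [f for f in self.model.features if f not in self.retained]
        if dropped:
            lines.append("")
            lines.append(f"not retained: {', '.join(dropped[:8])}"
                         + (" ..." if len(dropped) > 8 else ""))
        lines.append("")
        lines.append("threshold rule: Youden's J on observed score midpoints")
        return "\n".join(lines)

    # -- plots -------------------------------------------------------------

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in self.retained:
            r = self.roc[name]
            ax.plot(r.fpr, r.tpr, label=f"{name} (AUC {r.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        return ax

    def plot_calibration(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in self.retained:
            bins = self.calibration[name].bins
            xs = [b[0] for b in bins]
            ys = [b[1] for b in bins]
            ax.plot(xs, ys, "o-", label=name)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="perfectly calibrated")
        ax.set_xlabel("mean predicted probability")
        ax.set_ylabel("fraction of positives")
        ax.legend(fontsize=7)
        return ax

    def plot_decision_curves(self, ax=None, report_range=(0.10, 0.70)):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in self.retained:
            c = self.decision_curves[name]
            sel = (c.thresholds >= report_range[0]) & (c.thresholds <= report_range[1])
            ax.plot(c.thresholds[sel], c.model[sel], label=name)
        if self.retained:
            c = next(iter(self.decision_curves.values()))
            sel = (c.thresholds >= report_range[0]) & (c.thresholds <= report_range[1])
            ax.plot(c.thresholds[sel], c.treat_all[sel], "k-", lw=0.8, label="treat all")
            ax.plot(c.thresholds[sel], c.treat_none[sel], "k:", lw=0.8, label="treat none")
        ax.set_xlabel("threshold probability")
        ax.set_ylabel("net benefit")
        ax.legend(fontsize=7)
        return ax

    # -- serialisation -----------------------------------------------------

    def to_report(self) -> dict:
        """JSON-serialisable diagnostics report."""
        report = {
            "n_lesions": int(len(self.labels)),
            "n_positive": int(self.labels.sum()),
            "selection": self.selection.reset_index().to_dict(orient="records"),
            "retained": self.retained,
            "features": {},
            "delong_p": {f"{a}|{b}": p for (a, b), (_, _, _, p) in self.delong.items()},
            "threshold_rule": "youden",
        }
        for name in self.retained:
            r = self.roc[name]
            hl = self.calibration[name]
            c = self.decision_curves[name]
            report["features"][name] = {
                "threshold": r.threshold,
                "auc": r.auc,
                "metrics": r.metrics,
                "confusion": vars(r.confusion),
                "hosmer_lemeshow": {
                    "statistic": hl.statistic,
                    "p_value": hl.p_value,
                    "df": hl.df,
                    "n_bins": hl.n_bins,
                    "bins": hl.bins,
                },
                "probability_info": self.probability_info[name],
                "net_benefit": {
                    "thresholds": c.thresholds.tolist(),
                    "model": c.model.tolist(),
                    "treat_all": c.treat_all.tolist(),
                },
            }
        return report
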