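"""Study-level model: density-integrated centrality vs clinical outcome.

`ConnectomeCentralityModel` is built from a cohort of raw streamline-count
connectomes plus a clinical table, in the spirit of a statsmodels model:
construction validates and binds the data, `fit()` runs the analysis and
returns a `CentralityResults` object carrying estimates, p-values, effect
sizes and diagnostics, with a `summary()` table and writers.

The fitted analysis comprises:

* primary — permutation t-tests of integrated degree and betweenness at the
  bilateral piriform ROIs, drug-resistant vs drug-sensitive, Bonferroni
  alpha = family_alpha / (#nodes x #metrics);
* correlations — Spearman rho of each primary node x metric against epilepsy
  duration (and a control correlation against age at MRI);
* regression — OLS adjustment of the left-primary-node degree for clinical
  covariates (resistance + duration; then + sex, laterality, MRI-lesion
  coding, onset age);
* exploratory — the same group test and duration correlation at every
  network node, Benjamini-Hochberg corrected across nodes;
* surgery — permutation tests of candidate-node centrality between ILAE-1
  (seizure-free) and non-ILAE-1 operated subjects with >= 1 year follow-up,
  at alpha = family_alpha / 10.

One global seed expands into independent per-test seeds through a stable
hash of (seed, section, node, metric), so no two tests share a permutation
stream and every reported p-value can be reproduced by re-running the
underlying test with its logged seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cohort import ClinicalRecord, RawConnectome, read_cohort
from .config import AnalysisConfig
from .metrics import subject_centrality
from .stats import (
    RegressionResult,
    bonferroni_alpha,
    cohens_d,
    fdr_bh,
    ols_adjust,
    permutation_two_sample,
    spearman,
)
from .synthetic import derive_seed

SECTIONS = ("primary", "correlations", "regression", "exploratory", "surgery")


@dataclass(frozen=True)
class GroupTestResult:
    node: str
    metric: str
    t_statistic: float
    p_value: float
    cohens_d: float
    n_permutations: int
    exhaustive: bool
    alpha: float
    n_a: int
    n_b: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class CorrelationResult:
    node: str
    metric: str
    covariate: str
    rho: float
    p_value: float
    n: int
    alpha: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class ConnectomeCentralityModel:
    """Centrality group-difference model for one connectome cohort."""

    def __init__(
        self,
        connectomes: list[RawConnectome],
        clinical: list[ClinicalRecord],
        config: AnalysisConfig | None = None,
    ):
        if not connectomes:
            raise ValueError("empty cohort")
        self.config = config or AnalysisConfig()
        ref = connectomes[0].labels
        for c in connectomes[1:]:
            if c.labels != ref:
                raise ValueError(f"label mismatch for subject {c.subject_id}")
        missing_primary = set(self.config.primary_nodes) - set(ref)
        if missing_primary:
            raise ValueError(f"primary nodes not in matrices: {sorted(missing_primary)}")
        by_id = {r.subject_id: r for r in clinical}
        if len(by_id) != len(clinical):
            raise ValueError("duplicate subject ids in clinical records")
        missing = [c.subject_id for c in connectomes if c.subject_id not in by_id]
        if missing:
            raise ValueError(f"no clinical record for subjects: {missing}")
        self.connectomes = list(connectomes)
        self.clinical = [by_id[c.subject_id] for c in connectomes]
        self.labels = ref
        self._centrality_cache: dict[str, pd.DataFrame] | None = None
        self._fragmentation: dict[str, tuple[int, ...]] = {}

    @classmethod
    def from_directory(
        cls,
        matrix_dir: str | Path,
        clinical_table: str | Path,
        config: AnalysisConfig | None = None,
    ) -> "ConnectomeCentralityModel":
        connectomes, clinical = read_cohort(matrix_dir, clinical_table)
        return cls(connectomes, clinical, config)

    @classmethod
    def from_cohort(cls, cohort, config: AnalysisConfig | None = None):
        """Build directly from a SyntheticCohort."""
        return cls(cohort.connectomes, cohort.clinical, config)

    # -- centrality ---------------------------------------------------------

    def centralities(self) -> dict[str, pd.DataFrame]:
        """Per-metric (subjects x nodes) integrated-centrality tables."""
        if self._centrality_cache is None:
            cfg = self.config
            tables: dict[str, list[np.ndarray]] = {m: [] for m in cfg.metrics}
            for conn in self.connectomes:
                sc = subject_centrality(
                    conn,
                    low=cfg.density_low,
                    high=cfg.density_high,
                    step=cfg.density_step,
                    metrics=cfg.metrics,
                )
                if "degree" in tables:
                    tables["degree"].append(sc.degree.values)
                if "betweenness" in tables:
                    tables["betweenness"].append(sc.betweenness.values)
                if sc.fragmented_densities:
                    self._fragmentation[conn.subject_id] = sc.fragmented_densities
            ids = [c.subject_id for c in self.connectomes]
            self._centrality_cache = {
                m: pd.DataFrame(np.vstack(v), index=ids, columns=self.labels)
                for m, v in tables.items()
            }
        return self._centrality_cache

    # -- grouping helpers ---------------------------------------------------

    def _group_masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        resistant = np.array(
            [r.drug_resistant is True for r in self.clinical], dtype=bool
        )
        responsive = np.array(
            [r.drug_resistant is False for r in self.clinical], dtype=bool
        )
        unlabeled = ~(resistant | responsive)
        return resistant, responsive, unlabeled

    def _group_test(
        self, values: np.ndarray, seed: int, alpha: float, node: str, metric: str
    ) -> GroupTestResult:
        resistant, responsive, _ = self._group_masks()
        a, b = values[resistant], values[responsive]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 subjects per group")
        res = permutation_two_sample(
            a, b, n_permutations=self.config.n_permutations, seed=seed
        )
        return GroupTestResult(
            node=node,
            metric=metric,
            t_statistic=res.t_statistic,
            p_value=res.p_value,
            cohens_d=cohens_d(a, b),
            n_permutations=res.n_permutations,
            exhaustive=res.exhaustive,
            alpha=alpha,
            n_a=len(a),
            n_b=len(b),
            seed=seed,
        )

    # -- fit ----------------------------------------------------------------

    def fit(self, sections: tuple[str, ...] = SECTIONS) -> "CentralityResults":
        unknown = set(sections) - set(SECTIONS)
        if unknown:
            raise ValueError(f"unknown sections {sorted(unknown)}")
        cfg = self.config
        cent = self.centralities()
        resistant, responsive, unlabeled = self._group_masks()

        primary: list[GroupTestResult] = []
        correlations: list[CorrelationResult] = []
        regressions: dict[str, RegressionResult] = {}
        exploratory: dict[str, pd.DataFrame] = {}
        exploratory_duration: dict[str, pd.DataFrame] = {}
        surgery: list[GroupTestResult] = []
        surgery_note = None

        n_primary_tests = len(cfg.primary_nodes) * len(cfg.metrics)
        alpha_primary = bonferroni_alpha(cfg.family_alpha, n_primary_tests)

        if "primary" in sections:
            for node in cfg.primary_nodes:
                for metric in cfg.metrics:
                    seed = derive_seed(cfg.seed, "primary", node, metric)
                    values = cent[metric][node].to_numpy()
                    primary.append(
                        self._group_test(values, seed, alpha_primary, node, metric)
                    )

        duration = np.array(
            [
                np.nan if r.duration_years is None else r.duration_years
                for r in self.clinical
            ]
        )
        age = np.array([r.age_at_mri for r in self.clinical])
        labeled = resistant | responsive

        if "correlations" in sections:
            has_duration = labeled & np.isfinite(duration)
            for node in cfg.primary_nodes:
                for metric in cfg.metrics:
                    values = cent[metric][node].to_numpy()
                    rho, p = spearman(values[has_duration], duration[has_duration])
                    correlations.append(
                        CorrelationResult(
                            node=node,
                            metric=metric,
                            covariate="duration_years",
                            rho=rho,
                            p_value=p,
                            n=int(has_duration.sum()),
                            alpha=alpha_primary,
                        )
                    )
                    rho_a, p_a = spearman(values[labeled], age[labeled])
                    correlations.append(
                        CorrelationResult(
                            node=node,
                            metric=metric,
                            covariate="age_at_mri",
                            rho=rho_a,
                            p_value=p_a,
                            n=int(labeled.sum()),
                            alpha=alpha_primary,
                        )
                    )

        if "regression" in sections and "degree" in cfg.metrics:
            y = cent["degree"][cfg.primary_nodes[0]].to_numpy()[labeled]
            sub = [r for r, keep in zip(self.clinical, labeled) if keep]
            base = {
                "drug_resistant": np.array(
                    [1.0 if r.drug_resistant else 0.0 for r in sub]
                ),
                "duration_years": np.array(
                    [np.nan if r.duration_years is None else r.duration_years for r in sub]
                ),
            }
            regressions["resistance_duration"] = ols_adjust(y, base)
            full = dict(base)
            full["sex_female"] = np.array(
                [1.0 if r.sex == "female" else 0.0 for r in sub]
            )
            # laterality dummy-coded against a 'left' reference
            for level in ("right", "bilateral", "unclear"):
                full[f"laterality_{level}"] = np.array(
                    [1.0 if r.laterality == level else 0.0 for r in sub]
                )
            full["lesion_dummy"] = np.array([float(r.lesion_dummy) for r in sub])
            full["onset_age"] = np.array([r.onset_age for r in sub])
            # constant covariates (absent factor levels, uniform lesion
            # status) are collinear with the intercept and dropped
            for name in list(full):
                if name not in base and np.ptp(full[name]) == 0:
                    del full[name]
            regressions["full_covariates"] = ols_adjust(y, full)

        if "exploratory" in sections:
            for metric in cfg.metrics:
                table = cent[metric]
                rows = []
                for node in self.labels:
                    seed = derive_seed(cfg.seed, "exploratory", metric, node)
                    values = table[node].to_numpy()
                    a, b = values[resistant], values[responsive]
                    res = permutation_two_sample(
                        a, b, n_permutations=cfg.n_permutations, seed=seed
                    )
                    rows.append(
                        {
                            "node": node,
                            "t_statistic": res.t_statistic,
                            "cohens_d": cohens_d(a, b),
                            "p_raw": res.p_value,
                            "seed": seed,
                        }
                    )
                frame = pd.DataFrame(rows).set_index("node")
                frame["p_fdr"] = fdr_bh(frame["p_raw"].to_numpy())
                frame["m_comparisons"] = len(self.labels)
                exploratory[metric] = frame

                has_duration = labeled & np.isfinite(duration)
                drows = []
                for node in self.labels:
                    rho, p = spearman(
                        table[node].to_numpy()[has_duration], duration[has_duration]
                    )
                    drows.append({"node": node, "rho": rho, "p_raw": p})
                dframe = pd.DataFrame(drows).set_index("node")
                dframe["p_fdr"] = fdr_bh(dframe["p_raw"].to_numpy())
                dframe["m_comparisons"] = len(self.labels)
                exploratory_duration[metric] = dframe

        if "surgery" in sections:
            alpha_surgery = bonferroni_alpha(
                cfg.family_alpha, cfg.surgery_family_size
            )
            evaluable = np.array(
                [r.outcome_evaluable for r in self.clinical], dtype=bool
            )
            free = evaluable & np.array(
                [r.ilae_class == 1 for r in self.clinical], dtype=bool
            )
            not_free = evaluable & ~free
            if free.sum() < 2 or not_free.sum() < 2:
                surgery_note = (
                    "not evaluable: need >= 2 subjects in each surgical-outcome "
                    f"group (ILAE-1: {int(free.sum())}, other: {int(not_free.sum())})"
                )
            else:
                for node in cfg.surgery_nodes:
                    if node not in self.labels:
                        raise ValueError(f"surgery node {node!r} not in matrices")
                    for metric in cfg.metrics:
                        seed = derive_seed(cfg.seed, "surgery", node, metric)
                        values = cent[metric][node].to_numpy()
                        a, b = values[free], values[not_free]
                        res = permutation_two_sample(
                            a, b, n_permutations=cfg.n_permutations, seed=seed
                        )
                        surgery.append(
                            GroupTestResult(
                                node=node,
                                metric=metric,
                                t_statistic=res.t_statistic,
                                p_value=res.p_value,
                                cohens_d=cohens_d(a, b),
                                n_permutations=res.n_permutations,
                                exhaustive=res.exhaustive,
                                alpha=alpha_surgery,
                                n_a=int(free.sum()),
                                n_b=int(not_free.sum()),
                                seed=seed,
                            )
                        )

        import scipy
        import statsmodels

        diagnostics = {
            "n_subjects_total": len(self.connectomes),
            "n_drug_resistant": int(resistant.sum()),
            "n_drug_responsive": int(responsive.sum()),
            "n_excluded_missing_resistance": int(unlabeled.sum()),
            "n_missing_duration": int(np.isnan(duration[labeled]).sum()),
            "fragmentation": {
                sid: list(dens) for sid, dens in sorted(self._fragmentation.items())
            },
            "small_sample_exhaustive": any(t.exhaustive for t in primary),
            "versions": {
                "connectocentric": _pkg_version,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
            },
            "config": cfg.to_dict(),
        }

        return CentralityResults(
            model=self,
            primary=primary,
            correlations=correlations,
            regressions=regressions,
            exploratory=exploratory,
            exploratory_duration=exploratory_duration,
            surgery=surgery,
            surgery_note=surgery_note,
            diagnostics=diagnostics,
        )


@dataclass
class CentralityResults:
    """Fitted results: tests, effect sizes, tables, diagnostics."""

    model: ConnectomeCentralityModel
    primary: list[GroupTestResult]
    correlations: list[CorrelationResult]
    regressions: dict[str, RegressionResult]
    exploratory: dict[str, pd.DataFrame]
    exploratory_duration: dict[str, pd.DataFrame]
    surgery: list[GroupTestResult]
    surgery_note: str | None
    diagnostics: dict

    # -- accessors -----------------------------------------------------------

    def primary_result(self, node: str, metric: str) -> GroupTestResult:
        for r in self.primary:
            if r.node == node and r.metric == metric:
                return r
        raise KeyError((node, metric))

    def top_nodes(self, metric: str, by: str = "cohens_d") -> pd.DataFrame:
        """Exploratory table sorted by descending effect size."""
        return self.exploratory[metric].sort_values(by, ascending=False)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        lines = []
        d = self.diagnostics
        lines.append("Connectome centrality analysis")
        lines.append("=" * 64)
        lines.append(
            f"subjects: {d['n_subjects_total']} "
            f"(resistant {d['n_drug_resistant']}, responsive {d['n_drug_responsive']}, "
            f"resistance unknown {d['n_excluded_missing_resistance']})"
        )
        cfg = d["config"]
        lines.append(
            f"densities: {cfg['density_low']}-{cfg['density_high']}% "
            f"step {cfg['density_step']}%; permutations: {cfg['n_permutations']}"
        )
        if self.primary:
            lines.append("")
            lines.append(
                f"Primary tests (drug-resistant vs drug-sensitive), "
                f"alpha = {self.primary[0].alpha:g}"
            )
            lines.append(
                f"{'node':<24}{'metric':<14}{'t':>8}{'d':>8}{'p':>10}  sig"
            )
            for r in self.primary:
                flag = "*" if r.p_value < r.alpha else ""
                lines.append(
                    f"{r.node:<24}{r.metric:<14}{r.t_statistic:>8.3f}"
                    f"{r.cohens_d:>8.3f}{r.p_value:>10.5f}  {flag}"
                )
        if self.correlations:
            lines.append("")
            lines.append("Spearman correlations")
            lines.append(
                f"{'node':<24}{'metric':<14}{'covariate':<16}{'rho':>8}{'p':>10}"
            )
            for c in self.correlations:
                lines.append(
                    f"{c.node:<24}{c.metric:<14}{c.covariate:<16}"
                    f"{c.rho:>8.3f}{c.p_value:>10.5f}"
                )
        for name, reg in self.regressions.items():
            lines.append("")
            lines.append(
                f"OLS [{name}]: adj R^2 = {reg.adj_r_squared:.3f}, "
                f"F = {reg.f_statistic:.3f} (p = {reg.f_p_value:.4f}), "
                f"df = {reg.df_model}, n = {reg.n_used} "
                f"({reg.n_dropped} dropped)"
            )
            for term, coef, t, p in zip(
                reg.terms, reg.coefficients, reg.t_values, reg.p_values
            ):
                lines.append(f"  {term:<22}{coef:>12.4f}{t:>9.3f}{p:>10.4f}")
        if self.surgery:
            lines.append("")
            lines.append(
                f"Surgery subanalysis (ILAE-1 vs other), "
                f"alpha = {self.surgery[0].alpha:g}"
            )
            for r in self.surgery:
                lines.append(
                    f"{r.node:<24}{r.metric:<14}{r.t_statistic:>8.3f}"
                    f"{r.cohens_d:>8.3f}{r.p_value:>10.5f}"
                )
        elif self.surgery_note:
            lines.append("")
            lines.append(f"Surgery subanalysis {self.surgery_note}")
        if d["fragmentation"]:
            lines.append("")
            lines.append(
                f"WARNING: {len(d['fragmentation'])} subject(s) fragmented "
                "within the density sweep"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def reg_dict(r: RegressionResult) -> dict:
            return {
                "terms": list(r.terms),
                "coefficients": list(r.coefficients),
                "t_values": list(r.t_values),
                "p_values": list(r.p_values),
                "adj_r_squared": r.adj_r_squared,
                "f_statistic": r.f_statistic,
                "f_p_value": r.f_p_value,
                "df_model": r.df_model,
                "df_resid": r.df_resid,
                "n_used": r.n_used,
                "n_dropped": r.n_dropped,
            }

        return {
            "primary": [r.to_dict() for r in self.primary],
            "correlations": [c.to_dict() for c in self.correlations],
            "regressions": {k: reg_dict(v) for k, v in self.regressions.items()},
            "exploratory": {
                m: f.reset_index().to_dict("records")
                for m, f in self.exploratory.items()
            },
            "exploratory_duration": {
                m: f.reset_index().to_dict("records")
                for m, f in self.exploratory_duration.items()
            },
            "surgery": [r.to_dict() for r in self.surgery],
            "surgery_note": self.surgery_note,
            "diagnostics": self.diagnostics,
        }

    def save(self, directory: str | Path) -> None:
        """Write report.json plus per-section CSV tables and a log."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        if self.primary:
            pd.DataFrame([r.to_dict() for r in self.primary]).to_csv(
                directory / "primary.csv", index=False
            )
        if self.correlations:
            pd.DataFrame([c.to_dict() for c in self.correlations]).to_csv(
                directory / "correlations.csv", index=False
            )
        for metric, frame in self.exploratory.items():
            frame.to_csv(directory / f"exploratory_{metric}.csv")
        for metric, frame in self.exploratory_duration.items():
            frame.to_csv(directory / f"exploratory_duration_{metric}.csv")
        if self.surgery:
            pd.DataFrame([r.to_dict() for r in self.surgery]).to_csv(
                directory / "surgery.csv", index=False
            )
        (directory / "diagnostics.log").write_text(self.summary() + "\n")
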