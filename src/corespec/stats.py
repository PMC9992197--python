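"""Group statistics: normality gate, Kruskal-Wallis comparisons, multiple
testing control, clinical correlations, and summary-statistic t-tests.

The analysis per (ROI, band) cell is a three-group Kruskal-Wallis omnibus
test followed by pairwise Mann-Whitney contrasts with Bonferroni
adjustment (x3 pairs); Benjamini-Hochberg FDR is then applied across the
26 ROIs within each (band, contrast) family, matching the per-band
reporting of the study design.  Correlations between clinical covariates
and spectral power use Pearson when both variables pass a Shapiro-Wilk
normality gate and Spearman otherwise, with BH-FDR within each
(group, covariate, band) family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, MissingDataError
from .rois import ROI_NAMES

GROUP_ORDER = ("CI", "CNI", "HC")
CONTRASTS = (("CI", "HC"), ("CNI", "HC"), ("CI", "CNI"))
CLINICAL_COVARIATES = ("onset_age", "course_months", "seizure_count")

DEFAULT_ALPHA = 0.05
REPORTING_CUT = 0.005  # listing threshold used for the headline tables


# ---------------------------------------------------------------------------
# elementary tests


def shapiro_wilk_gate(
    *samples: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> list[dict]:
    """Shapiro-Wilk normality verdict per sample.

    Returns one dict per sample with keys ``W``, ``p``, ``normal``,
    ``degenerate``.  A constant sample is flagged degenerate (and
    non-normal) rather than crashing.
    """
    results = []
    for sample in samples:
        x = np.asarray(sample, dtype=float)
        if x.size < 3:
            raise ConfigurationError("Shapiro-Wilk needs at least 3 values")
        if np.ptp(x) == 0:
            results.append(
                {"W": float("nan"), "p": float("nan"),
                 "normal": False, "degenerate": True}
            )
            continue
        w, p = sp_stats.shapiro(x)
        results.append(
            {"W": float(w), "p": float(p), "normal": bool(p > alpha),
             "degenerate": False}
        )
    return results


def _kw_h_from_ranksums(rank_sums: np.ndarray, sizes: np.ndarray, n: int) -> np.ndarray:
    return 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes, axis=-1) - 3.0 * (n + 1)


def kw_permutation_null(sizes: tuple[int, ...]) -> np.ndarray:
    """Exact permutation distribution of the KW statistic for tie-free data.

    For continuous data the ranks are always 1..N, so the null distribution
    of H depends only on the group sizes; it is enumerated once over all
    distinct partitions of the ranks into the groups.
    """
    n = int(sum(sizes))
    if n > 14:
        raise ConfigurationError(
            f"exact enumeration limited to total n <= 14, got {n}"
        )
    ranks = np.arange(1, n + 1, dtype=float)
    sizes_arr = np.array(sizes, dtype=float)
    h_values = []
    indices = list(range(n))
    for combo1 in itertools.combinations(indices, sizes[0]):
        rest1 = [i for i in indices if i not in set(combo1)]
        s1 = ranks[list(combo1)].sum()
        if len(sizes) == 2:
            s2 = ranks[rest1].sum()
            h_values.append(
                _kw_h_from_ranksums(np.array([s1, s2]), sizes_arr, n)
            )
            continue
        for combo2 in itertools.combinations(rest1, sizes[1]):
            s2 = ranks[list(combo2)].sum()
            s_rest = ranks.sum() - s1 - s2
            if len(sizes) == 3:
                h_values.append(
                    _kw_h_from_ranksums(np.array([s1, s2, s_rest]), sizes_arr, n)
                )
            else:
                raise ConfigurationError("exact enumeration supports 2-3 groups")
    return np.sort(np.asarray(h_values, dtype=float))


def kruskal_wallis(
    *groups: np.ndarray, method: str = "auto", mid_p: bool = False
) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its p-value.

    ``method="chi2"`` uses the chi-square reference distribution;
    ``"exact"`` enumerates the permutation null (tie-free data, total
    n <= 14); ``"auto"`` picks exact for total n <= 10.  The exact p is
    the conservative P(H >= h); ``mid_p=True`` returns the Lancaster
    mid-p (P(H > h) + P(H = h)/2), the standard convention when comparing
    the discrete permutation null with a continuous reference.
    All-identical values return (0, 1) by convention.
    """
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ConfigurationError("every group needs at least one value")
    total_n = sum(a.size for a in arrays)
    if total_n < 3:
        raise ConfigurationError("need at least 3 values in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    if method == "auto":
        method = "exact" if total_n <= 10 else "chi2"
    h, p_chi2 = sp_stats.kruskal(*arrays)
    if method == "chi2":
        return float(h), float(p_chi2)
    if method != "exact":
        raise ConfigurationError(f"unknown method {method!r}")
    if np.unique(pooled).size != pooled.size:
        raise ConfigurationError("exact permutation p requires tie-free data")
    null = kw_permutation_null(tuple(a.size for a in arrays))
    ge = np.mean(null >= float(h) - 1e-12)
    if mid_p:
        eq = np.mean(np.abs(null - float(h)) <= 1e-12)
        return float(h), float(ge - eq / 2.0)
    return float(h), float(ge)


def pairwise_posthoc(
    group_samples: dict[str, np.ndarray],
    method: str = "bonferroni",
) -> dict[tuple[str, str], dict[str, float]]:
    """Pairwise two-sample Mann-Whitney tests with Bonferroni adjustment.

    Adjusted p is the raw p times the number of pairs, clipped at 1.
    """
    if method != "bonferroni":
        raise ConfigurationError(f"unsupported adjustment {method!r}")
    names = list(group_samples)
    if len(names) < 2:
        raise ConfigurationError("need at least 2 groups for post-hoc tests")
    pairs = list(itertools.combinations(names, 2))
    out: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in pairs:
        xa = np.asarray(group_samples[a], dtype=float)
        xb = np.asarray(group_samples[b], dtype=float)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            u, p = float(xa.size * xb.size / 2.0), 1.0
        else:
            u, p = sp_stats.mannwhitneyu(xa, xb, alternative="two-sided")
        out[(a, b)] = {
            "U": float(u),
            "p_raw": float(p),
            "p_adjusted": float(min(1.0, p * len(pairs))),
        }
    return out


def bh_fdr(
    p_values: np.ndarray, q: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def clinical_correlation(
    clinical: np.ndarray,
    power: np.ndarray,
    gate_alpha: float = DEFAULT_ALPHA,
) -> tuple[float, float, str]:
    """Correlation between a clinical covariate and spectral power.

    Pearson if both variables pass the Shapiro-Wilk gate, Spearman
    otherwise; returns (R, p, method).
    """
    x = np.asarray(clinical, dtype=float)
    y = np.asarray(power, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ConfigurationError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigurationError("zero variance in a correlation input")
    gates = shapiro_wilk_gate(x, y, alpha=gate_alpha)
    if gates[0]["normal"] and gates[1]["normal"]:
        r, p = sp_stats.pearsonr(x, y)
        return float(r), float(p), "pearson"
    r, p = sp_stats.spearmanr(x, y)
    return float(r), float(p), "spearman"


def summary_ttest(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "welch",
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    ``variant`` is ``"welch"`` (unequal variances, default) or
    ``"pooled"``.  Returns (t, df, p).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ConfigurationError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("group sizes must be at least 2")
    if variant not in ("welch", "pooled"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "pooled"
    t, p = sp_stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df), float(p)


# ---------------------------------------------------------------------------
# full report


@dataclass
class StatReport:
    """Per-(ROI, band) comparison results and clinical correlations."""

    tests: pd.DataFrame          # omnibus + pairwise rows
    correlations: pd.DataFrame   # clinical correlation rows
    alpha: float = DEFAULT_ALPHA
    reporting_cut: float = REPORTING_CUT
    settings: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "tests": directory / "stats_tests.csv",
            "correlations": directory / "stats_correlations.csv",
        }
        self.tests.to_csv(paths["tests"], index=False)
        self.correlations.to_csv(paths["correlations"], index=False)
        return paths

    @classmethod
    def load(cls, directory: str | Path) -> "StatReport":
        directory = Path(directory)
        return cls(
            tests=pd.read_csv(directory / "stats_tests.csv"),
            correlations=pd.read_csv(directory / "stats_correlations.csv"),
        )

    def rejection_set(
        self, contrast: str, band: str, criterion: str = "p_fdr"
    ) -> list[str]:
        """ROIs rejected at alpha for one (contrast, band) family."""
        sub = self.tests[
            (self.tests["contrast"] == contrast) & (self.tests["band"] == band)
        ]
        return sub.loc[sub[criterion] <= self.alpha, "roi"].tolist()

    def summary(self, max_rows: int = 40) -> str:
        """Human-readable digest of the strongest effects."""
        sub = self.tests[self.tests["contrast"] != "omnibus"]
        hits = sub[sub["reject_005"]].sort_values("p_raw")
        lines = [
            f"{len(hits)} (ROI, band, contrast) results below "
            f"p < {self.reporting_cut:g} (raw):"
        ]
        for _, row in hits.head(max_rows).iterrows():
            lines.append(
                f"  {row['band']:<11s} {row['roi']:<7s} {row['contrast']:<7s} "
                f"p={row['p_raw']:.2e} (FDR {row['p_fdr']:.2e})"
            )
        return "\n".join(lines)


def _cell_matrix(power_table: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "group", "roi", "band", "value"}
    missing_cols = required - set(power_table.columns)
    if missing_cols:
        raise MissingDataError(f"power table lacks columns {sorted(missing_cols)}")
    counts = power_table.groupby(["roi", "band"])["subject_id"].count()
    if counts.nunique() > 1:
        bad = counts[counts != counts.max()].index.tolist()
        raise MissingDataError(f"incomplete (roi, band) cells: {bad}")
    return power_table


def run_stats(
    power_table: pd.DataFrame,
    manifest: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    reporting_cut: float = REPORTING_CUT,
    kw_method: str = "chi2",
    correlate: bool = True,
) -> StatReport:
    """Full statistics layer over a long-format relative power table.

    ``power_table`` columns: subject_id, group, roi, band, value (complete
    over subjects x 26 ROIs x bands).  ``manifest`` carries one row per
    subject with the clinical covariates.  See the module docstring for the
    multiple-testing structure.
    """
    table = _cell_matrix(power_table)
    bands = list(dict.fromkeys(table["band"]))
    groups_present = [g for g in GROUP_ORDER if g in set(table["group"])]

    rows = []
    for band in bands:
        band_tbl = table[table["band"] == band]
        for roi in ROI_NAMES:
            cell = band_tbl[band_tbl["roi"] == roi]
            samples = {
                g: cell.loc[cell["group"] == g, "value"].to_numpy()
                for g in groups_present
            }
            h, p_kw = kruskal_wallis(*samples.values(), method=kw_method)
            rows.append(
                {"roi": roi, "band": band, "contrast": "omnibus",
                 "H": h, "p_raw": p_kw, "p_bonf": np.nan,
                 "omnibus_significant": p_kw <= alpha}
            )
            if len(groups_present) >= 2:
                posthoc = pairwise_posthoc(samples)
                for (a, b), res in posthoc.items():
                    rows.append(
                        {"roi": roi, "band": band, "contrast": f"{a}-{b}",
                         "H": np.nan, "p_raw": res["p_raw"],
                         "p_bonf": res["p_adjusted"],
                         "omnibus_significant": p_kw <= alpha}
                    )
    tests = pd.DataFrame(rows)

    # BH-FDR within each (band, contrast) family of 26 ROI tests
    tests["p_fdr"] = np.nan
    for (band, contrast), idx in tests.groupby(["band", "contrast"]).groups.items():
        p_adj, _ = bh_fdr(tests.loc[idx, "p_raw"].to_numpy(), q=alpha)
        tests.loc[idx, "p_fdr"] = p_adj
    tests["reject_05"] = tests["p_fdr"] <= alpha
    tests["reject_005"] = tests["p_raw"] <= reporting_cut

    corr_rows = []
    if correlate:
        man = manifest.set_index("subject_id")
        for group in ("CI", "CNI"):
            if group not in groups_present:
                continue
            for covariate in CLINICAL_COVARIATES:
                if covariate not in man.columns:
                    continue
                for band in bands:
                    for roi in ROI_NAMES:
                        cell = table[
                            (table["group"] == group)
                            & (table["band"] == band)
                            & (table["roi"] == roi)
                        ].set_index("subject_id")
                        clin = man.loc[cell.index, covariate].to_numpy(dtype=float)
                        power = cell["value"].to_numpy()
                        ok = np.isfinite(clin)
                        if ok.sum() < 4 or np.ptp(clin[ok]) == 0:
                            continue
                        r, p, method = clinical_correlation(clin[ok], power[ok])
                        corr_rows.append(
                            {"group": group, "covariate": covariate,
                             "roi": roi, "band": band,
                             "R": r, "p_raw": p, "method": method}
                        )
    correlations = pd.DataFrame(
        corr_rows,
        columns=["group", "covariate", "roi", "band", "R", "p_raw", "method"],
    )
    if len(correlations):
        correlations["p_fdr"] = np.nan
        grouping = correlations.groupby(["group", "covariate", "band"]).groups
        for _, idx in grouping.items():
            p_adj, _ = bh_fdr(correlations.loc[idx, "p_raw"].to_numpy(), q=alpha)
            correlations.loc[idx, "p_fdr"] = p_adj
        correlations["reject_05"] = correlations["p_fdr"] <= alpha
    else:
        correlations["p_fdr"] = pd.Series(dtype=float)
        correlations["reject_05"] = pd.Series(dtype=bool)

    return StatReport(
        tests=tests,
        correlations=correlations,
        alpha=alpha,
        reporting_cut=reporting_cut,
        settings={"kw_method": kw_method, "alpha": alpha,
                  "fdr_family": "per band x contrast across 26 ROIs"},
    )
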