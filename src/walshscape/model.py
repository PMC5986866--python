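"""Statsmodels-style front end: a study model fitted to one landscape.

:class:`LandscapeStudy` bundles a landscape with the analysis settings
(log transform, zero fill, permutation replicates, seed).  ``fit()`` runs the
full pipeline — preprocessing, Walsh decomposition, best-m residual sequence
with optional truncation by experimental variance, Kendall tau-b against the
combinatoric expectation and the permutation test — and returns a
:class:`LandscapeStudyResults` carrying every intermediate artifact and a
``summary()`` table.  :class:`StudySet` fits a collection of studies, applies
the Holm correction across them and reports the cross-study G-test of
P-value uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import approximation, preprocess, stats, transform
from .landscape import Landscape, read_landscape, landscape_from_table
from .nk import count_maxima

__all__ = ["LandscapeStudy", "LandscapeStudyResults", "StudySet", "StudySetResults",
           "run_study", "run_study_set"]


class LandscapeStudy:
    """Declining-influence analysis of one combinatorially complete landscape.

    Parameters
    ----------
    landscape : Landscape
        Complete landscape (any row order is fine if built via the readers).
    log_transform : bool
        Natural-log transform fitness (and map variances) before analysis.
    zero_fill : float
        Replacement for log of zero fitness.
    n_reps : int
        Permutation-test replicates.
    seed : int
        Seed for the permutation null sampler.
    method : str
        "sample" (default) or "exact" permutation null.
    name : str
        Label used in summary tables.
    """

    def __init__(
        self,
        landscape: Landscape,
        *,
        log_transform: bool = False,
        zero_fill: float = preprocess.DEFAULT_ZERO_FILL,
        n_reps: int = stats.DEFAULT_N_REPS,
        seed: int = 0,
        method: str = "sample",
        name: str = "landscape",
    ) -> None:
        self.landscape = landscape
        self.log_transform = log_transform
        self.zero_fill = zero_fill
        self.n_reps = n_reps
        self.seed = seed
        self.method = method
        self.name = name

    @classmethod
    def from_file(cls, path, **kwargs) -> "LandscapeStudy":
        io_keys = {"sep", "genotype_col", "fitness_col", "variance_col", "nrep_col"}
        io_kwargs = {k: kwargs.pop(k) for k in list(kwargs) if k in io_keys}
        return cls(read_landscape(path, **io_kwargs), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "LandscapeStudy":
        io_keys = {"genotype_col", "fitness_col", "variance_col", "nrep_col"}
        io_kwargs = {k: kwargs.pop(k) for k in list(kwargs) if k in io_keys}
        return cls(landscape_from_table(df, **io_kwargs), **kwargs)

    def fit(self) -> "LandscapeStudyResults":
        ls = self.landscape
        if self.log_transform:
            ls = preprocess.log_transform_landscape(ls, self.zero_fill)

        var_summary = None
        threshold = None
        if ls.var is not None and np.any(ls.var > 0):
            var_summary = preprocess.experimental_variance_fraction(ls)
            threshold = var_summary.exp_var_fraction

        spectrum = transform.walsh_forward(ls)
        seq = approximation.residual_sequence(ls, threshold)
        per_order = approximation.per_order_summary(seq, spectrum)
        study = stats.permutation_test(
            seq.observed_orders,
            ls.L,
            n_reps=self.n_reps,
            seed=self.seed,
            method=self.method,
        )
        return LandscapeStudyResults(
            model=self,
            processed=ls,
            spectrum=spectrum,
            fourier=transform.fourier_spectrum(spectrum),
            approx=seq,
            per_order=per_order,
            study=study,
            n_maxima=count_maxima(ls),
            var_summary=var_summary,
        )


@dataclass
class LandscapeStudyResults:
    """Fitted study: decomposition, ranking, truncation and test results."""

    model: LandscapeStudy
    processed: Landscape
    spectrum: transform.Spectrum
    fourier: transform.FourierSpectrum
    approx: approximation.ApproxSequence
    per_order: pd.DataFrame
    study: stats.StudyResult
    n_maxima: int
    var_summary: preprocess.VarianceSummary | None

    @property
    def tau_b(self) -> float:
        return self.study.tau_b

    @property
    def p_uncorrected(self) -> float:
        return self.study.p_uncorrected

    @property
    def m_star(self) -> int:
        return self.approx.m_star

    def summary(self) -> str:
        s = self.study
        lines = [
            f"Landscape study: {self.model.name}",
            "=" * 46,
            f"loci (L)                    {self.processed.L}",
            f"genotypes                   {self.processed.n_genotypes}",
            f"local maxima                {self.n_maxima}",
            f"log transform               {self.model.log_transform}",
        ]
        if self.var_summary is not None:
            lines.append(
                f"experimental var fraction   {self.var_summary.exp_var_fraction:.4f}"
            )
        lines += [
            f"retained terms (m*)         {s.m_star}",
            f"discarded terms (j)         {s.j}",
            f"Kendall tau_b               {s.tau_b:.4f}",
            f"P (one-tailed, {s.n_reps:g} reps)  {s.p_display}",
            "-" * 46,
            "reduction in residual variance by order:",
            self.per_order.to_string(index=False, float_format="%.4f"),
        ]
        return "\n".join(lines)

    def plot_residual_sequence(self, ax=None):
        """Residual-variance fraction of the best-m model against m.

        Markers are colored by the epistatic order of the m-th term added;
        the truncation point, if any, is drawn as a vertical line.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        seq = self.approx
        m = np.arange(1, 2**seq.L + 1)
        sc = ax.scatter(m, seq.resid_fraction[1:], c=seq.ranked_orders,
                        cmap="viridis", s=18)
        ax.set_xlabel("terms in model (m)")
        ax.set_ylabel("residual variance fraction")
        if seq.m_star < 2**seq.L:
            ax.axvline(seq.m_star + 0.5, ls="--", color="grey")
        plt.colorbar(sc, ax=ax, label="epistatic order")
        return ax


def run_study(study: LandscapeStudy) -> LandscapeStudyResults:
    """Functional alias: fit one study."""
    return study.fit()


class StudySet:
    """A collection of studies analysed jointly."""

    def __init__(self, studies: list[LandscapeStudy],
                 g_test_edges=stats.DEFAULT_G_TEST_EDGES) -> None:
        if not studies:
            raise ValueError("study set is empty")
        self.studies = list(studies)
        self.g_test_edges = g_test_edges

    def fit(self) -> "StudySetResults":
        results = [s.fit() for s in self.studies]
        p = np.array([r.p_uncorrected for r in results])
        p_corr = stats.holm_correct(p)
        for r, pc in zip(results, p_corr):
            r.study.p_corrected = float(pc)
        g = df = None
        if len(results) > 1:
            g, df = stats.g_test_uniformity(p, self.g_test_edges)
        return StudySetResults(results=results, g=g, df=df)


@dataclass
class StudySetResults:
    results: list[LandscapeStudyResults]
    g: float | None
    df: int | None

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            s = r.study
            rows.append(
                {
                    "dataset": r.model.name,
                    "L": r.processed.L,
                    "maxima": r.n_maxima,
                    "m_star": s.m_star,
                    "tau_b": s.tau_b,
                    "p_uncorrected": s.p_uncorrected,
                    "p_display": s.p_display,
                    "stars": stats.significance_stars(s.p_corrected),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        out = [self.table.to_string(index=False, float_format="%.4f")]
        if self.g is not None:
            out.append(
                f"G-test of P-value uniformity: G = {self.g:.2f}, df = {self.df}, "
                f"P = {stats.g_test_pvalue(self.g, self.df):.3g}"
            )
        return "\n".join(out)


def run_study_set(studies: list[LandscapeStudy], **kwargs) -> StudySetResults:
    """Functional alias: fit a set of studies with joint corrections."""
    return StudySet(studies, **kwargs).fit()
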