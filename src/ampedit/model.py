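"""Model/Results interface over the editing-outcome pipeline.

:class:`AmpliconEditingModel` is built from paired reads plus an allele
description; ``fit()`` runs the full aggregation pipeline (merge pairs,
trim to reference boundaries, count unique sequences, align and classify)
and returns an :class:`EditingResults` carrying the estimated outcome
proportions, their binomial uncertainties, per-stage diagnostics and a
``summary()`` table — the estimand being the multinomial composition
(HDR, NHEJ, unmodified) of the sequenced allele population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .amplicon import AlleleSet
from .align import ScoringScheme
from .classify import (
    CLASSES,
    ClassificationPolicy,
    EditingSummary,
    UniqueSequenceTable,
    aggregate_unique,
    classify_table,
    summarize_editing,
)
from .merge import MergeStats, merge_pairs
from .simulate import SimulationConfig, simulate_dataset
from .trim import TrimStats, trim_reads

__all__ = ["AmpliconEditingModel", "EditingResults"]


class AmpliconEditingModel:
    """Editing-outcome model for one amplicon sample.

    Parameters
    ----------
    pairs : iterable of ReadPair
        The sample's paired reads (consumed on ``fit``).
    alleles : AlleleSet
        Mutant reference, wild type and HDR allele with edit-site
        annotation.
    min_overlap, max_error_rate
        Pair-merging knobs (minimum overlap length; tolerated mismatch
        fraction inside the overlap).
    anchor_len, max_anchor_errors
        Boundary-trimming knobs (reference-terminus anchor length; error
        budget per anchor).
    policy, scheme
        Classification policy and alignment scoring scheme.
    """

    def __init__(
        self,
        pairs,
        alleles: AlleleSet,
        *,
        min_overlap: int = 15,
        max_error_rate: float = 0.1,
        anchor_len: int = 15,
        max_anchor_errors: int = 2,
        policy: ClassificationPolicy = ClassificationPolicy(),
        scheme: ScoringScheme = ScoringScheme(),
    ) -> None:
        self.pairs = pairs
        self.alleles = alleles
        self.min_overlap = min_overlap
        self.max_error_rate = max_error_rate
        self.anchor_len = anchor_len
        self.max_anchor_errors = max_anchor_errors
        self.policy = policy
        self.scheme = scheme

    @classmethod
    def from_fastq(cls, path_r1, path_r2, alleles: AlleleSet, **kwargs):
        from .io import read_fastq_pairs

        return cls(list(read_fastq_pairs(path_r1, path_r2)), alleles, **kwargs)

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig, alleles: AlleleSet, **kwargs
    ):
        """Build model and ground truth from a simulated library."""
        pairs, truth = simulate_dataset(config, alleles)
        model = cls(pairs, alleles, **kwargs)
        model.truth = truth
        return model

    def fit(self) -> "EditingResults":
        merged, merge_stats = merge_pairs(
            self.pairs, self.min_overlap, self.max_error_rate
        )
        trimmed, trim_stats = trim_reads(
            merged, self.alleles.mutant, self.anchor_len, self.max_anchor_errors
        )
        table = aggregate_unique(t.bases for t in trimmed)
        classify_table(table, self.alleles, self.policy, self.scheme)
        summary = summarize_editing(
            table,
            n_total_pairs=merge_stats.n_pairs,
            n_merged=merge_stats.n_merged,
            n_anchored=trim_stats.n_anchored,
            reference_name=self.alleles.mutant.name,
        )
        return EditingResults(
            self, summary, table, merge_stats, trim_stats, merged, trimmed
        )


@dataclass
class EditingResults:
    """Fitted editing-outcome estimates with uncertainties and diagnostics."""

    model: AmpliconEditingModel
    editing_summary: EditingSummary
    unique_table: UniqueSequenceTable
    merge_stats: MergeStats
    trim_stats: TrimStats
    merged_reads: list = field(default_factory=list)
    trimmed_reads: list = field(default_factory=list)

    @property
    def proportions(self) -> pd.Series:
        s = self.editing_summary
        return pd.Series(
            {c: s.class_counts[c] / s.n_classified for c in CLASSES},
            name="proportion",
        )

    @property
    def percentages(self) -> pd.Series:
        return (self.proportions * 100).rename("percent")

    @property
    def bse(self) -> pd.Series:
        """Binomial standard errors of the class proportions."""
        n = self.editing_summary.n_classified
        p = self.proportions
        return np.sqrt(p * (1 - p) / n).rename("bse")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wilson score intervals for each class proportion."""
        n = self.editing_summary.n_classified
        rows = {}
        for c in CLASSES:
            lo, hi = proportion_confint(
                self.editing_summary.class_counts[c], n, alpha=alpha, method="wilson"
            )
            rows[c] = (lo, hi)
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def top_sequences(self, n: int = 20) -> pd.DataFrame:
        return self.unique_table.to_frame().head(n)

    def summary(self) -> str:
        s = self.editing_summary
        ci = self.conf_int()
        lines = [
            "Amplicon editing-outcome estimates",
            "=" * 58,
            f"Reference: {s.reference_name}",
            f"Read pairs: {s.n_total_pairs}   merged: {s.n_merged}   "
            f"anchored: {s.n_anchored}   classified: {s.n_classified}",
            f"Unique sequences: {len(self.unique_table)}",
            "-" * 58,
            f"{'class':<12}{'reads':>8}{'percent':>10}{'se':>8}{'95% CI':>18}",
        ]
        for c in CLASSES:
            pct = 100 * self.proportions[c]
            se = 100 * self.bse[c]
            lines.append(
                f"{c:<12}{s.class_counts[c]:>8}{pct:>9.1f}%{se:>7.2f}%"
                f"   [{100 * ci.loc[c, 'lower']:5.1f}%, {100 * ci.loc[c, 'upper']:5.1f}%]"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_outcomes(self, ax=None):
        """Bar chart of class percentages with binomial error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        pct = self.percentages
        err = 100 * self.bse
        ax.bar(pct.index, pct.values, yerr=err.values, capsize=3,
               color=["#4c72b0", "#dd8452", "#55a868"])
        ax.set_ylabel("% of classified reads")
        ax.set_ylim(0, 100)
        return ax
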