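"""Two-step classification of sample pairs into five assembly processes.

Step 1 uses betaNTI (phylogenetic null): values >= +2 indicate
heterogeneous selection, <= -2 homogeneous selection (thresholds
inclusive). Step 2, applied when |betaNTI| < 2 (or betaNTI is undefined),
uses RC_bray: > +0.95 dispersal limitation, < -0.95 homogenizing dispersal
(thresholds exclusive), otherwise the pair is undominated (mainly drift).

Fractions are aggregated per run and, with bootstrap rarefaction, averaged
across bootstrap replicates (mean of per-boot fractions; the pooled
fraction over all boot x pair rows is reported alongside). Per-pair labels
can differ between bootstraps; the per-boot table is always exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .io import OtuTable, RarefiedEnsemble, ValidationError
from .nullmodels import beta_nti_matrix, rc_bray_matrix
from .phylo import cophenetic_distances

__all__ = [
    "PROCESS_LABELS",
    "AnalysisConfig",
    "ProcessFractions",
    "BootstrapProcessResult",
    "classify_pair",
    "process_fractions",
    "infer_processes",
    "bootstrap_process_fractions",
]

PROCESS_LABELS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


@dataclass
class AnalysisConfig:
    """Constants of the analysis; defaults are the study's choices."""

    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    n_null: int = 999
    n_boot: int = 100
    rarefaction_depth: int = 5557
    top_n: int | None = 1000
    occupancy_min: int = 4          # occupancy > 3
    indval_alpha: float = 0.05
    indval_min_relabund: float = 1e-4  # 0.01 %
    n_perm: int = 999
    seed: int = 0
    shared_null: bool = True
    abundance_weighted: bool = True

    def __post_init__(self):
        if self.bnti_threshold <= 0 or self.rc_threshold <= 0:
            raise ValidationError("thresholds must be > 0")
        if self.rc_threshold >= 1:
            raise ValidationError("rc_threshold must be < 1")
        for name in ("n_null", "n_boot", "rarefaction_depth", "occupancy_min", "n_perm"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProcessFractions:
    """Per-process fractions over a set of classified pairs (sum to 1)."""

    fractions: dict
    n_pairs: int

    def __post_init__(self):
        if self.n_pairs > 0:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"fractions sum to {total}, not 1")

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.fractions.get(k, 0.0) for k in PROCESS_LABELS})


def classify_pair(bnti, rc, cfg: AnalysisConfig | None = None) -> str:
    """Five-way process label for one sample pair.

    ``bnti`` may be None/NaN (degenerate null): such pairs carry no
    selection signal and fall through to the RC step.
    """
    cfg = cfg or AnalysisConfig()
    if rc is None or not np.isfinite(rc) or not (-1.0 <= rc <= 1.0):
        raise ValidationError(f"rc must be in [-1, 1], got {rc}")
    if bnti is not None and np.isfinite(bnti):
        if bnti >= cfg.bnti_threshold:
            return "heterogeneous_selection"
        if bnti <= -cfg.bnti_threshold:
            return "homogeneous_selection"
    if rc > cfg.rc_threshold:
        return "dispersal_limitation"
    if rc < -cfg.rc_threshold:
        return "homogenizing_dispersal"
    return "undominated"


def _merge_pairs(bnti_results: pd.DataFrame, rc_results: pd.DataFrame) -> pd.DataFrame:
    key = ["sample_a", "sample_b"]
    ka = set(map(tuple, bnti_results[key].itertuples(index=False)))
    kb = set(map(tuple, rc_results[key].itertuples(index=False)))
    if ka != kb:
        raise ValidationError(f"betaNTI and RC cover different pairs: {ka ^ kb}")
    return bnti_results.merge(rc_results[key + ["bc_obs", "rc"]], on=key, validate="1:1")


def process_fractions(
    bnti_results: pd.DataFrame,
    rc_results: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
) -> ProcessFractions:
    """Classify every pair and report per-label fractions."""
    cfg = cfg or AnalysisConfig()
    merged = _merge_pairs(bnti_results, rc_results)
    labels = [classify_pair(r.bnti, r.rc, cfg) for r in merged.itertuples()]
    n = len(labels)
    fr = {lab: labels.count(lab) / n for lab in PROCESS_LABELS}
    return ProcessFractions(fractions=fr, n_pairs=n)


def infer_processes(
    table: OtuTable,
    dist: DistanceMatrix,
    cfg: AnalysisConfig | None = None,
    rng=None,
) -> pd.DataFrame:
    """betaNTI + RC + classification for one table; long per-pair frame."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(rng if rng is not None else cfg.seed)
    bnti = beta_nti_matrix(
        table, dist, n_null=cfg.n_null, rng=rng,
        shared_null=cfg.shared_null, abundance_weighted=cfg.abundance_weighted,
    )
    rc = rc_bray_matrix(table, n_null=cfg.n_null, rng=rng, shared_null=cfg.shared_null)
    merged = _merge_pairs(bnti, rc)
    merged["label"] = [classify_pair(r.bnti, r.rc, cfg) for r in merged.itertuples()]
    return merged


@dataclass
class BootstrapProcessResult:
    """Bootstrap-aggregated process inference.

    Attributes
    ----------
    per_pair : DataFrame
        One row per (boot, pair): bnti, rc, label, ...
    per_boot_fractions : DataFrame
        boot x process fractions (each row sums to 1).
    mean_fractions : ProcessFractions
        Arithmetic mean of per-boot fractions (the headline summary).
    pooled_fractions : ProcessFractions
        Fractions over all boot x pair rows pooled together.
    modal_labels : DataFrame
        Per pair, the modal label across boots and its support.
    """

    per_pair: pd.DataFrame
    per_boot_fractions: pd.DataFrame
    mean_fractions: ProcessFractions
    pooled_fractions: ProcessFractions
    modal_labels: pd.DataFrame = field(repr=False, default=None)


def bootstrap_process_fractions(
    ensemble: RarefiedEnsemble,
    tree: TreeNode,
    cfg: AnalysisConfig | None = None,
) -> BootstrapProcessResult:
    """Run betaNTI + RC + classification on every bootstrap table.

    Seeds for the null models derive deterministically from the ensemble
    seed and the boot index via named sub-streams, so reruns are
    bit-reproducible and boots are independent.
    """
    cfg = cfg or AnalysisConfig()
    dist = cophenetic_distances(tree)
    frames = []
    for b, tab in enumerate(ensemble.tables):
        rng = np.random.default_rng(np.random.SeedSequence(ensemble.seed, spawn_key=(101, b)))
        merged = infer_processes(tab, dist, cfg, rng=rng)
        merged.insert(0, "boot", b)
        frames.append(merged)
    per_pair = pd.concat(frames, ignore_index=True)

    per_boot = (
        per_pair.groupby("boot")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=PROCESS_LABELS, fill_value=0.0)
    )
    mean_fr = per_boot.mean(axis=0)
    mean_fr = mean_fr / mean_fr.sum()
    n_pairs = int(per_pair.groupby("boot").size().iloc[0])
    pooled_counts = per_pair["label"].value_counts(normalize=True)
    pooled = {lab: float(pooled_counts.get(lab, 0.0)) for lab in PROCESS_LABELS}

    modal = (
        per_pair.groupby(["sample_a", "sample_b"])["label"]
        .agg(lambda s: s.value_counts().idxmax())
        .rename("modal_label")
        .reset_index()
    )
    support = (
        per_pair.groupby(["sample_a", "sample_b"])["label"]
        .agg(lambda s: s.value_counts().max() / len(s))
        .rename("modal_support")
        .reset_index()
    )
    modal = modal.merge(support, on=["sample_a", "sample_b"])

    return BootstrapProcessResult(
        per_pair=per_pair,
        per_boot_fractions=per_boot,
        mean_fractions=ProcessFractions(dict(mean_fr), n_pairs=n_pairs),
        pooled_fractions=ProcessFractions(pooled, n_pairs=len(per_pair)),
        modal_labels=modal,
    )
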