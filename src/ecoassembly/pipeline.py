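"""End-to-end orchestration: rarefy -> signal check -> betaNTI -> RC ->
classify -> aggregate -> environmental statistics -> IndVal -> ordination.

One :func:`run_pipeline` call analyses one dataset, optionally split into
groups by metadata columns (e.g. season x fraction); every stage writes its
result as labelled TSV into the output directory, and a JSON manifest
records the configuration, input checksums, per-stage timings and output
checksums. Summary TSVs are byte-stable under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .envstats import (
    env_correlations,
    env_distance,
    geo_distance,
    mantel,
    niche_values,
    pcoa,
    permanova,
    phylo_signal_correlogram,
    regress_bnti_env,
)
from .indicators import habitat_preference_counts, indval
from .io import (
    OtuTable,
    SampleMetadata,
    ValidationError,
    bootstrap_rarefy,
    classify_habitat,
    observed_richness,
    read_metadata,
    read_otu_table,
    read_tree,
    top_n_subcommunity,
)
from .phylo import cophenetic_distances, weighted_unifrac
from .processes import AnalysisConfig, PROCESS_LABELS, bootstrap_process_fractions

logger = logging.getLogger("ecoassembly")

_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _fractions_frame(result) -> pd.DataFrame:
    per_boot = result.per_boot_fractions
    rows = []
    for label in PROCESS_LABELS:
        rows.append(
            {
                "process": label,
                "mean_fraction": per_boot[label].mean(),
                "sd_fraction": per_boot[label].std(ddof=1) if len(per_boot) > 1 else 0.0,
                "pooled_fraction": result.pooled_fractions.fractions.get(label, 0.0),
            }
        )
    return pd.DataFrame(rows)


def _group_key(row, columns) -> str:
    return "+".join(str(row[c]) for c in columns) if columns else "all"


def run_pipeline(
    otu_path,
    tree_path,
    metadata_path,
    cfg: AnalysisConfig | None = None,
    group_by=None,
    out_dir="ecoassembly_out",
) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON).

    ``group_by`` is an optional list of metadata columns; the null-model
    analysis is run separately within each group (mirroring designs such as
    season x nucleic-acid fraction), while environmental screens use each
    group's samples. With no grouping all samples form one set.
    """
    cfg = cfg or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "group_by": list(group_by) if group_by else [],
        "inputs": {},
        "stages": {},
        "outputs": {},
        "warnings": [],
    }
    timings = manifest["stages"]

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("read_inputs"):
        table = read_otu_table(otu_path)
        tree = read_tree(tree_path)
        metadata = read_metadata(metadata_path)
        metadata.require_samples(table.sample_ids)
        for p, key in ((otu_path, "otu_table"), (tree_path, "tree"), (metadata_path, "metadata")):
            manifest["inputs"][key] = _sha256(Path(p))

    logger.info(
        "constants: n_null=%d n_boot=%d depth=%d bnti_threshold=%.3g rc_threshold=%.3g "
        "occupancy_min=%d indval_min_relabund=%.3g indval_alpha=%.3g n_perm=%d top_n=%s",
        cfg.n_null, cfg.n_boot, cfg.rarefaction_depth, cfg.bnti_threshold,
        cfg.rc_threshold, cfg.occupancy_min, cfg.indval_min_relabund,
        cfg.indval_alpha, cfg.n_perm, cfg.top_n,
    )

    meta_aligned = metadata.aligned(table.sample_ids)
    if group_by:
        keys = meta_aligned.frame.apply(lambda r: _group_key(r, group_by), axis=1)
    else:
        keys = pd.Series("all", index=meta_aligned.frame.index)
    groups = {k: list(idx) for k, idx in keys.groupby(keys).groups.items()}

    outputs = manifest["outputs"]

    def register(path: Path):
        outputs[str(path.relative_to(out))] = _sha256(path)

    for gname, samples in sorted(groups.items()):
        gdir = out / gname
        gdir.mkdir(exist_ok=True)
        gtable = table.select_samples(samples).drop_empty_otus()
        gmeta = metadata.aligned(samples)
        gseed = int(
            np.random.SeedSequence(
                cfg.seed, spawn_key=(int(hashlib.sha256(gname.encode()).hexdigest()[:8], 16),)
            ).generate_state(1)[0]
            % 2**31
        )

        with stage(f"{gname}:rarefaction"):
            ensemble = bootstrap_rarefy(
                gtable, cfg.rarefaction_depth, cfg.n_boot, seed=gseed
            )
            richness = pd.DataFrame(
                [observed_richness(t) for t in ensemble.tables]
            )
            rich_out = pd.DataFrame(
                {
                    "sample_id": richness.columns,
                    "mean_richness": richness.mean(axis=0).to_numpy(),
                    "sd_richness": richness.std(axis=0, ddof=1).to_numpy()
                    if cfg.n_boot > 1
                    else 0.0,
                }
            )
            _write(rich_out, gdir / "richness.tsv")
            register(gdir / "richness.tsv")

        with stage(f"{gname}:phylo_signal"):
            dist_full = cophenetic_distances(tree)
            niches = niche_values(
                gtable, gmeta, occupancy_min=cfg.occupancy_min
            )
            rng = np.random.default_rng(np.random.SeedSequence(gseed, spawn_key=(21,)))
            try:
                classes = phylo_signal_correlogram(
                    niches, dist_full, n_perm=cfg.n_perm, rng=rng
                )
                sig = pd.DataFrame([vars(c) for c in classes])
                _write(sig, gdir / "phylo_signal.tsv")
                register(gdir / "phylo_signal.tsv")
                if not any(
                    c.tested and c.p_corrected < 0.05 and c.mantel_r > 0 for c in classes
                ):
                    msg = f"{gname}: no significant phylogenetic signal class"
                    warnings.warn(msg)
                    manifest["warnings"].append(msg)
            except ValidationError as e:
                msg = f"{gname}: phylogenetic signal not testable ({e})"
                warnings.warn(msg)
                manifest["warnings"].append(msg)

        with stage(f"{gname}:null_models"):
            result = bootstrap_process_fractions(ensemble, tree, cfg)
            _write(result.per_pair, gdir / "per_pair.tsv")
            _write(_fractions_frame(result), gdir / "process_fractions.tsv")
            _write(result.modal_labels, gdir / "modal_labels.tsv")
            for f in ("per_pair.tsv", "process_fractions.tsv", "modal_labels.tsv"):
                register(gdir / f)

        if cfg.top_n is not None and gtable.n_otus > cfg.top_n:
            with stage(f"{gname}:subcommunity"):
                sub = top_n_subcommunity(gtable, cfg.top_n)
                sub_depth = min(cfg.rarefaction_depth, int(sub.sample_sums.min()))
                sub_ens = bootstrap_rarefy(sub, sub_depth, cfg.n_boot, seed=gseed + 1)
                sub_res = bootstrap_process_fractions(sub_ens, tree, cfg)
                _write(
                    _fractions_frame(sub_res),
                    gdir / "process_fractions_subcommunity.tsv",
                )
                register(gdir / "process_fractions_subcommunity.tsv")

        with stage(f"{gname}:environment"):
            rng = np.random.default_rng(np.random.SeedSequence(gseed, spawn_key=(22,)))
            try:
                envd = env_distance(gmeta)
            except ValidationError:
                # drop constant variables (e.g. a uniform-environment design)
                envs = gmeta.env_matrix()
                keep = [c for c in envs.columns if envs[c].std(ddof=1) > 0]
                msg = f"{gname}: constant environmental variable(s) dropped"
                manifest["warnings"].append(msg)
                envd = env_distance(gmeta, keep)
            geod = geo_distance(gmeta)
            r_geo, p_geo = mantel(envd, geod, n_perm=cfg.n_perm, rng=rng)
            reg = regress_bnti_env(
                result.per_pair.groupby(["sample_a", "sample_b"], as_index=False)["bnti"]
                .mean(),
                envd,
            )
            corr = env_correlations(gmeta)
            env_summary = pd.DataFrame(
                [
                    {
                        "mantel_r_env_geo": r_geo,
                        "mantel_p_env_geo": p_geo,
                        "bnti_env_slope": reg.slope,
                        "bnti_env_intercept": reg.intercept,
                        "bnti_env_r_squared": reg.r_squared,
                        "bnti_env_p": reg.p,
                        "bnti_env_note": reg.note,
                        "n_significant_env_correlations": int(corr["significant"].sum()),
                    }
                ]
            )
            _write(env_summary, gdir / "environment_summary.tsv")
            _write(corr, gdir / "env_correlations.tsv")
            register(gdir / "environment_summary.tsv")
            register(gdir / "env_correlations.tsv")

        with stage(f"{gname}:indval"):
            habitats = {
                s: classify_habitat(gmeta.frame.loc[s, "salinity"]) for s in samples
            }
            if len(set(habitats.values())) >= 2:
                rng = np.random.default_rng(np.random.SeedSequence(gseed, spawn_key=(23,)))
                records = indval(
                    gtable,
                    habitats,
                    n_perm=cfg.n_perm,
                    min_relabund=cfg.indval_min_relabund,
                    rng=rng,
                )
                _write(records, gdir / "indval.tsv")
                register(gdir / "indval.tsv")
                counts = habitat_preference_counts(records, alpha=cfg.indval_alpha)
                _write(
                    pd.DataFrame(
                        [{"habitat": h, "n_otus": n} for h, n in sorted(counts.items())]
                    ),
                    gdir / "habitat_preference.tsv",
                )
                register(gdir / "habitat_preference.tsv")
            else:
                manifest["warnings"].append(
                    f"{gname}: single habitat class, IndVal skipped"
                )

        with stage(f"{gname}:ordination"):
            rng = np.random.default_rng(np.random.SeedSequence(gseed, spawn_key=(24,)))
            # mean weighted UniFrac over bootstrap tables
            acc = None
            for t in ensemble.tables:
                d = weighted_unifrac(t, tree)
                acc = d.data if acc is None else acc + d.data
            from skbio import DistanceMatrix

            mean_wu = DistanceMatrix(acc / ensemble.n_boot, ids=samples)
            coords, eigvals = pcoa(mean_wu)
            _write(coords.reset_index(names="sample_id"), gdir / "pcoa_coordinates.tsv")
            register(gdir / "pcoa_coordinates.tsv")
            habs = pd.Series(
                {s: classify_habitat(gmeta.frame.loc[s, "salinity"]) for s in samples}
            )
            counts_per_hab = habs.value_counts()
            testable = counts_per_hab[counts_per_hab >= 2]
            if len(testable) >= 2:
                keep = habs[habs.isin(testable.index)]
                sub_dm = mean_wu.filter(list(keep.index))
                res = permanova(sub_dm, keep, n_perm=cfg.n_perm, rng=rng)
                _write(
                    pd.DataFrame([vars(res)]), gdir / "permanova_habitat.tsv"
                )
                register(gdir / "permanova_habitat.tsv")
            else:
                manifest["warnings"].append(
                    f"{gname}: fewer than two testable habitat groups, PERMANOVA skipped"
                )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
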