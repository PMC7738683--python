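"""End-to-end orchestration: cohort -> deconfound -> three analysis arms.

``run_pipeline`` executes the full study workflow from one config: obtain a
cohort (simulated or loaded from the four TSV tables), clean each feature
block against the confound design, fit the hierarchical volume model, extract
and permutation-test the dominant PLS connectivity mode, compute the tract
association table, and write a machine-readable results bundle plus a
markdown report.  All stage seeds derive deterministically from the master
seed, so identical configs give bit-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import load_atlas, load_tract_catalog
from .config import PipelineConfig, stage_seed
from .deconfound import ConfoundRegressor, build_confound_matrix
from .hierarchical import HierarchicalVolumeModel, threshold_regions
from .io import read_cohort
from .pls import PLSPhenotypeMode
from .simulate import generate_cohort
from .tracts import TractAssociation

log = logging.getLogger("lonebrain")

__all__ = ["run_pipeline"]


class _StageWriter:
    """Writes stage outputs atomically: .partial until the stage succeeds."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.pending: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.out_dir / f"{name}.partial"
        self.pending.append(p)
        return p

    def commit(self) -> list[Path]:
        final = []
        for p in self.pending:
            target = p.with_suffix("")
            p.rename(target)
            final.append(target)
        self.pending.clear()
        return final


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except Exception as e:  # noqa: BLE001 - re-raise with stage label
                raise RuntimeError(f"stage '{name}' failed: {e}") from e

        return wrapped

    return deco


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@_stage("acquire")
def _acquire(cfg: PipelineConfig):
    atlas = load_atlas()
    catalog = load_tract_catalog()
    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        sim_cfg.seed = stage_seed(cfg.seed, "simulate")
        sc = generate_cohort(sim_cfg, atlas, catalog)
        return sc.cohort, sc.volumes, sc.fc_edges, sc.fa, sc.truth, atlas, catalog
    paths = cfg.inputs
    cohort, vol, fc, fa = read_cohort(
        paths["volumes"], paths["fc"], paths["fa"], paths["phenotypes"],
        atlas=atlas, catalog=catalog,
    )
    return cohort, vol, fc, fa, None, atlas, catalog


@_stage("deconfound")
def _deconfound(cfg, cohort, volumes, fc, fa):
    cm = build_confound_matrix(cohort, cfg.confounds)
    # volumes: residualize, then z-score (model expects unit-variance columns)
    vol_clean = ConfoundRegressor(standardize_output=True).fit_transform(
        volumes, confounds=cm
    )
    # edges: standardized across participants before cleaning; no re-z after
    fc_clean = ConfoundRegressor(
        standardize_first=True, standardize_output=False
    ).fit_transform(fc, confounds=cm)
    # FA: residualize only; correlation statistics are scale-invariant
    fa_clean = ConfoundRegressor(standardize_output=False).fit_transform(
        fa, confounds=cm
    )
    return vol_clean, fc_clean, fa_clean


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a results dict and writes the bundle to out_dir."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = _StageWriter(out_dir)
    results: dict = {}

    cohort, volumes, fc, fa, truth, atlas, catalog = _acquire(cfg)
    results["n"] = cohort.n
    results["prevalence"] = float(cohort.loneliness.mean())
    if truth is not None:
        with open(writer.path("truth.json"), "w") as f:
            json.dump(truth.to_dict(), f)
    writer.commit()

    vol_clean, fc_clean, fa_clean = _deconfound(cfg, cohort, volumes, fc, fa)

    y, sex, age = cohort.loneliness, cohort.sex, cohort.age

    @_stage("fit-volumes")
    def arm_volumes():
        vm = cfg.volume_model
        model = HierarchicalVolumeModel(
            kind=vm.kind,
            stratify_sex=cfg.stratify_sex,
            sigma_scale=vm.sigma_scale,
            lkj_eta=vm.lkj_eta,
            diagonal=vm.diagonal,
            chains=vm.chains,
            tune=vm.tune,
            draws=vm.draws,
            target_accept=vm.target_accept,
            max_treedepth=vm.max_treedepth,
            paper_settings=vm.paper_settings,
            seed=stage_seed(cfg.seed, "fit-volumes"),
        )
        model.fit(vol_clean, y, sex=sex, age=age, atlas=atlas)
        model.summary_.table.to_csv(
            writer.path("volume_summary.tsv"), sep="\t", index=False
        )
        writer.commit()
        results["volume"] = {
            "network_ranking": list(model.network_ranking_),
            "network_sigma_mean": model.summary_.network_sigma_mean,
            "max_rhat": model.max_rhat_,
            "flagged_regions": threshold_regions(model.summary_).to_dict("records"),
        }
        return model

    @_stage("fit-fc")
    def arm_fc(rows=None, tag=""):
        Xe = fc_clean if rows is None else fc_clean[rows]
        ye = y if rows is None else y[rows]
        pls = PLSPhenotypeMode(
            n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, f"fit-fc{tag}"),
        )
        pls.fit(Xe, ye)
        perm = pls.permutation_test(Xe, ye)
        blocks = pls.network_blocks(atlas)
        suffix = f"_{tag}" if tag else ""
        pd.DataFrame(
            {"edge": range(len(pls.x_weights_)), "weight": pls.x_weights_}
        ).to_csv(writer.path(f"fc_mode{suffix}.tsv"), sep="\t", index=False)
        pd.DataFrame(blocks, index=atlas.networks, columns=atlas.networks).to_csv(
            writer.path(f"fc_blocks{suffix}.tsv"), sep="\t"
        )
        with open(writer.path(f"fc_permutation{suffix}.json"), "w") as f:
            json.dump(
                {
                    "observed": perm.observed,
                    "p_value": perm.p_value,
                    "B": perm.B,
                    "null_stats": perm.null_stats.tolist(),
                },
                f,
            )
        writer.commit()
        results[f"fc{suffix}"] = {
            "mode_corr": pls.mode_corr_,
            "p_value": perm.p_value,
        }
        return pls

    @_stage("fit-tracts")
    def arm_tracts(rows=None, tag=""):
        Xt = fa_clean if rows is None else fa_clean[rows]
        yt = y if rows is None else y[rows]
        ta = TractAssociation(
            n_bootstrap=cfg.n_bootstrap, seed=stage_seed(cfg.seed, f"fit-tracts{tag}")
        )
        ta.fit(Xt, yt, catalog=catalog)
        suffix = f"_{tag}" if tag else ""
        ta.table_.to_csv(writer.path(f"tracts{suffix}.tsv"), sep="\t", index=False)
        writer.commit()
        results[f"tracts{suffix}"] = {
            "top_tracts": list(ta.top_tracts_),
            "top_rho": float(
                ta.table_.sort_values("rank")["pearson_rho"].iloc[0]
            ),
        }
        return ta

    arm_volumes()
    arm_fc()
    arm_tracts()
    if cfg.stratify_sex:
        for tag, mask in (("men", sex == 1), ("women", sex == 0)):
            arm_fc(rows=np.flatnonzero(mask), tag=tag)
            arm_tracts(rows=np.flatnonzero(mask), tag=tag)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg.to_yaml().encode()).hexdigest(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out_dir.iterdir())
            if p.suffix in (".tsv", ".json") and p.name != "manifest.json"
        },
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    (out_dir / "report.md").write_text(_render_report(results))
    results["manifest"] = manifest
    return results


def _render_report(results: dict) -> str:
    lines = ["# Loneliness multimodal analysis report", ""]
    lines.append(f"Cohort: n = {results['n']}, prevalence = {results['prevalence']:.3f}")
    if "volume" in results:
        v = results["volume"]
        lines += ["", "## Gray-matter volume arm", ""]
        lines.append(f"Max Rhat: {v['max_rhat']:.3f}")
        lines.append("")
        lines.append("| rank | network | posterior sigma mean |")
        lines.append("|---|---|---|")
        for i, net in enumerate(v["network_ranking"], 1):
            lines.append(f"| {i} | {net} | {v['network_sigma_mean'][net]:.4f} |")
        if v["flagged_regions"]:
            lines += ["", "Regions with 5-95% HPD excluding zero:", ""]
            lines.append("| region | group | mean | hpd5 | hpd95 | sign |")
            lines.append("|---|---|---|---|---|---|")
            for r in v["flagged_regions"]:
                lines.append(
                    f"| {r['parameter']} | {r['group']} | {r['mean']:.3f} "
                    f"| {r['hpd5']:.3f} | {r['hpd95']:.3f} | {r['flagged']} |"
                )
    for key in sorted(k for k in results if k.startswith("fc")):
        f = results[key]
        lines += ["", f"## Functional connectivity arm ({key})", ""]
        lines.append(
            f"Mode correlation rho = {f['mode_corr']:.4f}, permutation p = {f['p_value']:.4g}"
        )
    for key in sorted(k for k in results if k.startswith("tracts")):
        t = results[key]
        lines += ["", f"## White-matter tract arm ({key})", ""]
        lines.append(
            f"Top tracts: {', '.join(t['top_tracts'])} (top Pearson rho = {t['top_rho']:.4f})"
        )
    lines.append("")
    return "\n".join(lines)
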