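"""End-to-end experiment orchestration.

A run takes a connectome + receptor map (from files or the synthetic
generator), calibrates feedback inhibition under placebo, simulates both
conditions across repetitions with seeds derived deterministically from the
master seed, estimates the regional entropy topographies and their relative
changes, fits the three-way region partition, and optionally runs the
connectome null-model controls. Every output directory carries a manifest
(resolved config, input digests, per-stage status, per-repetition seeds) so
that identical config + seed reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dmf import calibrate_fic, simulate
from .entropy import (
    condition_contrast,
    group_summary,
    region_entropies,
    relative_change,
)
from .io import (
    read_connectome,
    read_metadata,
    read_receptor_map,
    write_connectome,
    write_metadata,
    write_params,
    write_receptor_map,
)
from .nulls import SurrogateSpec, surrogate_delta_h_experiment
from .params import Connectome, InvalidParameterError, ModelParameters, ReceptorMap
from .partition import (
    RegionFeatures,
    fit_partition_model,
    node_strength,
    optimize_partition,
    seed_partition,
)
from .synthetic import (
    SyntheticSpec,
    generate_connectome,
    generate_metadata,
    generate_receptor_map,
)

__all__ = ["RunConfig", "run_experiment"]

log = logging.getLogger("neuroentropy")


@dataclass
class RunConfig:
    """Configuration of one end-to-end experiment."""

    out_dir: str | Path = "neuroentropy_run"
    connectome_path: str | None = None
    receptors_path: str | None = None
    metadata_path: str | None = None
    synthetic: SyntheticSpec | None = None
    params: ModelParameters = field(default_factory=ModelParameters)
    n_repetitions: int = 5
    recalibrate_per_rep: bool = False
    run_partition: bool = True
    partition_n_iter: int = 2000
    run_nulls: bool = False
    null_schemes: tuple[str, ...] = ("RAND", "DPR", "DSPR")
    n_surrogates: int = 5
    surrogate_reps: int = 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["params"] = self.params.to_dict()
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        return d


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _rep_seed(master: int, rep: int, condition: str) -> int:
    """Deterministic per-repetition seed, distinct per condition."""
    tag = 0 if condition == "placebo" else 1
    return (master * 100003 + rep * 2 + tag) % (2**31)


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        con = generate_connectome(cfg.synthetic)
        rec = generate_receptor_map(cfg.synthetic, con)
        meta = generate_metadata(cfg.synthetic, con)
        return con, rec, meta, {}
    if cfg.connectome_path is None or cfg.receptors_path is None:
        raise InvalidParameterError(
            "provide either a synthetic spec or connectome + receptor files"
        )
    con = read_connectome(cfg.connectome_path)
    rec = read_receptor_map(cfg.receptors_path, labels=con.labels)
    meta = read_metadata(cfg.metadata_path) if cfg.metadata_path else None
    digests = {
        "connectome": _digest(Path(cfg.connectome_path)),
        "receptors": _digest(Path(cfg.receptors_path)),
    }
    if cfg.metadata_path:
        digests["metadata"] = _digest(Path(cfg.metadata_path))
    return con, rec, meta, digests


def run_experiment(cfg: RunConfig) -> dict:
    """Run the configured stages; write tables + manifest; return results.

    Returns a dict with the in-memory results (calibration, entropy stacks,
    delta-h, contrast, partition, null report) alongside the output paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "stages": {},
        "seeds": {},
    }
    results: dict = {"out_dir": out}

    def stage_done(name: str, **extra) -> None:
        manifest["stages"][name] = {"status": "ok", "t": round(time.time() - t0, 2), **extra}
        _write_manifest(out, manifest)

    def stage_failed(name: str, exc: Exception) -> None:
        manifest["stages"][name] = {"status": "failed", "error": str(exc)}
        _write_manifest(out, manifest)

    p = cfg.params
    try:
        con, rec, meta, digests = _load_inputs(cfg)
        manifest["inputs"] = digests
        if cfg.synthetic is not None:
            write_connectome(con, out / "connectome.csv")
            write_receptor_map(rec, out / "receptors.tsv", labels=con.labels)
            if meta is not None:
                write_metadata(meta, out / "metadata.tsv")
        write_params(p, out / "resolved_params.json")
        stage_done("load", n_regions=con.n_regions)
    except Exception as exc:
        stage_failed("load", exc)
        raise

    # --- calibration -----------------------------------------------------
    try:
        log.info("calibrating feedback inhibition (N=%d)", con.n_regions)
        cal = calibrate_fic(con, rec, p)
        np.savetxt(out / "j_fic.txt", cal.J_fic)
        results["calibration"] = cal
        stage_done("calibrate", n_iter=cal.n_iter,
                   worst_dev=float(np.abs(cal.achieved_rates - p.target_rate).max()))
    except Exception as exc:
        stage_failed("calibrate", exc)
        raise

    # --- simulate + entropy ----------------------------------------------
    try:
        h_stacks = {"placebo": [], "5ht2a": []}
        fit_rows = []
        for rep in range(cfg.n_repetitions):
            if cfg.recalibrate_per_rep and rep > 0:
                cal = calibrate_fic(con, rec, p.with_updates(seed=p.seed + rep))
            for cond in ("placebo", "5ht2a"):
                seed = _rep_seed(p.seed, rep, cond)
                manifest["seeds"][f"rep{rep}_{cond}"] = seed
                series = simulate(con, rec, p, cal.J_fic, cond, seed=seed)
                topo = region_entropies(series)
                h_stacks[cond].append(topo.h)
                for i, f in enumerate(topo.fits):
                    fit_rows.append(
                        {"region": con.labels[i], "condition": cond, "rep": rep,
                         "k": f.k, "theta": f.theta, "ks_stat": f.ks_stat,
                         "h": topo.h[i]}
                    )
            log.info("repetition %d/%d done", rep + 1, cfg.n_repetitions)
        h_pla = np.array(h_stacks["placebo"])
        h_2a = np.array(h_stacks["5ht2a"])
        pd.DataFrame(fit_rows).to_csv(out / "entropy.tsv", sep="\t", index=False)

        delta = relative_change(h_pla, h_2a)
        pd.DataFrame(
            {"region": con.labels, "mean": delta.delta_h, "sd": delta.sd}
        ).to_csv(out / "delta_h.tsv", sep="\t", index=False)
        contrast = condition_contrast(h_pla, h_2a)
        (out / "contrast.json").write_text(json.dumps(contrast, indent=2) + "\n")
        results.update(h_pla=h_pla, h_2a=h_2a, delta_h=delta, contrast=contrast)
        stage_done("entropy", n_repetitions=cfg.n_repetitions)
    except Exception as exc:
        stage_failed("entropy", exc)
        raise

    # --- group summaries ---------------------------------------------------
    if meta is not None and "lobe" in getattr(meta, "columns", ()):
        try:
            for col in ("lobe", "rsn"):
                if col in meta.columns:
                    gs = group_summary(delta, meta, group_col=col)
                    gs.to_csv(out / f"group_summary_{col}.tsv", sep="\t", index=False)
            stage_done("group_summary")
        except Exception as exc:  # non-fatal
            stage_failed("group_summary", exc)

    # --- partition ---------------------------------------------------------
    if cfg.run_partition:
        try:
            feats = RegionFeatures(
                strength=node_strength(con),
                density=rec.density,
                delta_h=delta.delta_h,
                labels=con.labels,
            )
            if meta is not None and "prior" in meta.columns:
                prior = list(meta.loc[meta["prior"].astype(bool), "region"])
            else:
                # fall back: top-strength quintile anchors the strength group
                k = max(2, con.n_regions // 5)
                prior = [con.labels[i] for i in np.argsort(feats.strength)[::-1][:k]]
            seeded = seed_partition(feats, prior)
            part = optimize_partition(
                feats, seeded, n_iter=cfg.partition_n_iter, rng=p.seed
            )
            fit = fit_partition_model(feats, part)
            pd.DataFrame({"region": con.labels, "label": part.labels}).to_csv(
                out / "partition.tsv", sep="\t", index=False
            )
            (out / "partition_model.json").write_text(
                json.dumps(
                    {
                        "r_squared": fit.r_squared,
                        "per_group_r_squared": fit.per_group_r_squared,
                        "coefficients": fit.coefficients,
                        "rank_deficient": fit.rank_deficient,
                    },
                    indent=2,
                )
                + "\n"
            )
            results.update(partition=part, partition_fit=fit)
            stage_done("partition", r_squared=fit.r_squared)
        except Exception as exc:
            stage_failed("partition", exc)
            raise

    # --- null models -------------------------------------------------------
    if cfg.run_nulls:
        try:
            null_report = {}
            for scheme in cfg.null_schemes:
                spec = SurrogateSpec(
                    scheme=scheme, n_surrogates=cfg.n_surrogates, seed=p.seed
                )
                res = surrogate_delta_h_experiment(
                    con, rec, spec, p, n_reps=cfg.surrogate_reps,
                    delta_h_original=delta.delta_h,
                )
                null_report[scheme] = {
                    "correlation": res["correlation"],
                    "delta_h_mean": res["delta_h_mean"].tolist(),
                }
                log.info("null scheme %s: corr=%.3f", scheme, res["correlation"])
            (out / "nulls.json").write_text(json.dumps(null_report, indent=2) + "\n")
            results["nulls"] = null_report
            stage_done("nulls")
        except Exception as exc:
            stage_failed("nulls", exc)
            raise

    _write_manifest(out, manifest)
    results["manifest"] = manifest
    return results


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
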