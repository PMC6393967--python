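"""End-to-end orchestration: clean → model → reconstruct → altall → score.

``run_all`` drives the whole branch-scoring analysis from a structured
configuration (YAML or dict), producing a run directory with every stage
output, a machine-readable manifest (resolved parameters, seed, input
checksums) and a log.  Re-running with the configuration recorded in a
manifest reproduces all outputs byte-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .altall import generate_all_libraries
from .epistasis import DMeasureParams, classify_branches, score_tree_epistasis
from .hygiene import clean_alignment
from .model import discrete_gamma, estimate_gamma_shape, estimate_relative_rates
from .reconstruct import marginal_posteriors
from .simulate import choose_shift_branch, simulate_evolution, simulate_yule_tree
from .structure import (
    TsvPredictor,
    classify_structural_branches,
    mock_predictor,
    score_tree_structure,
)

logger = logging.getLogger("stokeshift")

DEFAULTS: dict = {
    "seed": 0,
    "clean": {"max_site_gap": 0.8, "max_seq_gap": 0.75},
    "model": {
        "source": "estimated",  # estimated | jtt
        "alpha": None,  # None -> grid-estimated
        "ncat": 6,
        "identity_window": [0.2, 0.95],
    },
    "altall": {"pp_threshold": 0.1},
    "epistasis": {
        "steepness": 200.0,
        "factor": 2.0,
        "pp_square_variant": False,
        "flag_percentile": 95.0,
        "rfab_matrix": "estimated",  # estimated | jtt
        "include_leaf_branches": False,
    },
    "structure": {"predictor": "mock", "flag_percentile": 95.0, "pairing": "cross"},
    "simulate": {
        "n_taxa": 16,
        "length": 300,
        "height": 1.0,
        "alpha": 1.0,
        "ncat": 6,
        "shift": True,
    },
}


class PipelineError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("configuration file must hold a mapping")
    return cfg


def _merge(defaults: dict, given: dict) -> dict:
    out = copy.deepcopy(defaults)
    for k, v in given.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def resolve_config(config: dict) -> dict:
    cfg = _merge(DEFAULTS, config)
    has_input = "input" in config
    has_sim = "simulate" in config
    if not has_input and not has_sim:
        raise PipelineError(
            "configuration must provide either 'input' (alignment, tree) or "
            "a 'simulate' block"
        )
    if has_input:
        for key in ("alignment", "tree"):
            if key not in config["input"]:
                raise PipelineError(f"missing configuration key: input.{key}")
        cfg.pop("simulate", None)
    else:
        cfg.pop("input", None)
    return cfg


def assemble_branch_table(
    epi_df: pd.DataFrame, struct_dfs: dict[str, pd.DataFrame]
) -> sio.BranchScoreTable:
    """Merge per-metric classification frames into one row per branch."""
    frames = []
    for metric, df in [("epistasis", epi_df)] + list(struct_dfs.items()):
        renamed = df.rename(
            columns={
                "score": metric,
                "percentile": f"percentile_{metric}",
                "quartile": f"quartile_{metric}",
                "flag": f"flag_{metric}",
            }
        ).set_index(["parent", "child"])
        frames.append(renamed)
    merged = pd.concat(frames, axis=1).reset_index()
    merged = merged.sort_values(["parent", "child"], kind="mergesort").reset_index(
        drop=True
    )
    cols = ["parent", "child"]
    for m in sio.METRICS:
        for c in (m, f"percentile_{m}", f"quartile_{m}", f"flag_{m}"):
            if c in merged.columns:
                cols.append(c)
    return sio.BranchScoreTable(merged[cols])


def run_all(config: dict | str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline; returns the run directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = resolve_config(config)

    run_dir = Path(out_dir) if out_dir is not None else Path(cfg.get("output", "run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    stage = "setup"
    try:
        seed = int(cfg["seed"])
        checksums = {}

        stage = "inputs"
        if "input" in cfg:
            aln_path = Path(cfg["input"]["alignment"])
            tree_path = Path(cfg["input"]["tree"])
            aln = sio.read_alignment(aln_path)
            tree = sio.read_tree(tree_path)
            checksums["alignment"] = _sha256(aln_path)
            checksums["tree"] = _sha256(tree_path)
        else:
            sim = cfg["simulate"]
            tree = simulate_yule_tree(
                int(sim["n_taxa"]), seed=seed, height=float(sim["height"])
            )
            rates_sim = discrete_gamma(float(sim["alpha"]), int(sim["ncat"]))
            shifts = (
                frozenset({choose_shift_branch(tree, seed)})
                if sim["shift"]
                else frozenset()
            )
            aln, truth = simulate_evolution(
                tree,
                sio.ReversibleRateMatrix.jtt(),
                rates_sim,
                int(sim["length"]),
                seed=seed,
                shift_branches=shifts,
            )
            sio.write_alignment(aln, run_dir / "simulated.fasta")
            sio.write_tree(tree, run_dir / "simulated.nwk")
            pd.DataFrame(
                {
                    "node": list(truth.true_ancestors),
                    "sequence": list(truth.true_ancestors.values()),
                    "shift_branch": [
                        n in truth.shift_branches for n in truth.true_ancestors
                    ],
                }
            ).to_csv(run_dir / "simulated.truth.tsv", sep="\t", index=False)
            logger.info("simulated %d taxa x %d sites; shifts=%s",
                        aln.n_sequences, aln.length, sorted(shifts))

        stage = "clean"
        aln_clean, kept_sites, removed_ids = clean_alignment(
            aln, cfg["clean"]["max_site_gap"], cfg["clean"]["max_seq_gap"]
        )
        if removed_ids:
            tree = sio.prune_tree(tree, aln_clean.ids)
        sio.write_alignment(aln_clean, run_dir / "cleaned.fasta")
        pd.DataFrame({"kept_site": np.array(kept_sites) + 1}).to_csv(
            run_dir / "kept_sites.tsv", sep="\t", index=False
        )
        logger.info(
            "clean: kept %d/%d sites, removed %d sequences",
            len(kept_sites), aln.length, len(removed_ids),
        )

        stage = "estimate-model"
        if cfg["model"]["source"] == "jtt":
            matrix = sio.ReversibleRateMatrix.jtt()
        else:
            lo, hi = cfg["model"]["identity_window"]
            matrix = estimate_relative_rates(aln_clean, lo, hi)
        sio.write_rate_matrix(matrix, run_dir / "model.dat")
        alpha = cfg["model"]["alpha"]
        if alpha is None:
            alpha = estimate_gamma_shape(aln_clean, tree, matrix, cfg["model"]["ncat"])
            logger.info("estimated gamma shape alpha=%g", alpha)
        rates = discrete_gamma(float(alpha), int(cfg["model"]["ncat"]))

        stage = "reconstruct"
        profile = marginal_posteriors(aln_clean, tree, matrix, rates)
        profile.to_frame().to_csv(
            run_dir / "profiles.tsv", sep="\t", index=False, float_format="%.6g"
        )
        with open(run_dir / "map_ancestors.fasta", "w") as fh:
            for node in profile.nodes:
                fh.write(f">{node}\n{profile.map_sequence(node)}\n")

        stage = "altall"
        libraries = generate_all_libraries(profile, cfg["altall"]["pp_threshold"])
        for node, lib in libraries.items():
            sio.write_library(lib, run_dir / f"node_{node}.altall.fasta")
        logger.info("altall: %d libraries, max size %d",
                    len(libraries), max(len(l) for l in libraries.values()))

        stage = "score-epistasis"
        params = DMeasureParams(
            steepness=float(cfg["epistasis"]["steepness"]),
            factor=float(cfg["epistasis"]["factor"]),
            pp_square_variant=bool(cfg["epistasis"]["pp_square_variant"]),
        )
        rf_matrix = (
            sio.ReversibleRateMatrix.jtt()
            if cfg["epistasis"]["rfab_matrix"] == "jtt"
            else matrix
        )
        epi_scores = score_tree_epistasis(
            profile,
            tree,
            rf_matrix,
            params,
            include_leaf_branches=cfg["epistasis"]["include_leaf_branches"],
            aln=aln_clean,
        )
        epi_df = classify_branches(epi_scores, cfg["epistasis"]["flag_percentile"])

        stage = "score-structure"
        pred_spec = cfg["structure"]["predictor"]
        if pred_spec == "mock":
            predictor = mock_predictor
        elif isinstance(pred_spec, str) and pred_spec.startswith("tsv:"):
            predictor = TsvPredictor(pred_spec[4:])
        else:
            raise PipelineError(f"unknown predictor spec {pred_spec!r}")
        freqs = score_tree_structure(
            libraries, tree, predictor, pairing=cfg["structure"]["pairing"]
        )
        struct_dfs = classify_structural_branches(
            freqs, cfg["structure"]["flag_percentile"]
        )

        stage = "report"
        table = assemble_branch_table(epi_df, struct_dfs)
        sio.write_branch_scores(table, run_dir / "branch_scores.tsv")
        sio.write_annotated_tree(tree, table, run_dir / "annotated.nwk")

        manifest = {
            "config": cfg,
            "seed": seed,
            "input_checksums": checksums,
            "n_sequences": aln_clean.n_sequences,
            "n_sites": aln_clean.length,
            "alpha": float(alpha),
        }
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("run complete: %s", run_dir)
        return run_dir
    except Exception as exc:
        failed = run_dir / "failed"
        failed.mkdir(exist_ok=True)
        for item in list(run_dir.iterdir()):
            if item.name in ("failed", "run.log"):
                continue
            shutil.move(str(item), str(failed / item.name))
        logger.error("stage '%s' failed: %s", stage, exc)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
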