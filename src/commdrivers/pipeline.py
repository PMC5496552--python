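"""End-to-end orchestration of the three-step analysis.

Step 1 — per community: forward selection inside each abiotic block, a
two-component PLSR of the other community as the biotic block, then a
multiblock redundancy analysis with cross-validated dimensionality and
bootstrap tolerance intervals on the importance indices.

Step 2 — variation partitioning of each community between the combined
selected abiotic variables and the two biotic PLSR components.

Step 3 — matrix-level C-score tests on both communities plus pairwise
CL / Mean-Bayes screening on the generalist–common (G–C) and
specialist–host (S–H) submatrices.

Every random procedure consumes a named child seed derived from the master
seed, so a rerun with the same config is reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cdio
from .containers import BlockCollection, SiteSpeciesMatrix
from .exceptions import StepFailureError
from .mbra import (
    block_importance,
    bootstrap_intervals,
    mbra_fit,
    select_ncomp_cv,
    variable_importance,
)
from .cooccurrence import (
    bayes_m_filter,
    classify_pairs,
    ff_swap_null,
    matrix_level_test,
    pairs_to_frame,
    pairwise_test,
)
from .ordination import forward_select, plsr_fit
from .preprocess import (
    CommonPlantRule,
    build_pair_matrices,
    hellinger_transform,
    log_transform_cover,
    occupancy_filter,
    to_presence_absence,
)
from .synthetic import vineyard_profile
from .varpart import summarize_varpart, varpart2

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def child_seed(master: int, name: str) -> int:
    """Deterministic named child seed below 2**31."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    # inputs: either a simulation profile or file paths
    simulate: bool = True
    n_sites: int = 68
    n_plants: int = 120
    n_hoppers: int = 80
    coupling: float = 0.7
    plants_path: str | None = None
    hoppers_path: str | None = None
    blocks_dir: str | None = None
    blockmap_path: str | None = None
    meta_path: str | None = None
    hosts_path: str | None = None
    # transforms
    min_sites: int = 5
    log_base: float | None = None
    # forward selection
    alpha: float = 0.05
    selection_n_perm: int = 9999
    # mbRA
    h: int | str = "auto"
    h_max: int = 7
    cv_folds: int = 2
    cv_repeats: int = 100
    bootstrap_b: int = 1000
    interval_level: float = 0.95
    # varpart
    varpart_n_perm: int = 999
    # co-occurrence
    n_null: int = 1000
    burn_in: int = 30000
    thin: int = 1000
    adaptive_chain: bool = True  # scale burn-in/thin with matrix size
    n_bins: int = 20
    cl_level: float = 0.95
    common_top_n: int = 88
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyData:
    env: BlockCollection
    plants: SiteSpeciesMatrix
    hoppers: SiteSpeciesMatrix
    truth: object | None = None


def load_data(cfg: PipelineConfig) -> StudyData:
    if cfg.simulate:
        env, plants, hoppers, truth = vineyard_profile(
            cfg.seed,
            n_sites=cfg.n_sites,
            n_plants=cfg.n_plants,
            n_hoppers=cfg.n_hoppers,
            coupling=cfg.coupling,
        )
        return StudyData(env, plants, hoppers, truth)
    plants = cdio.read_community(cfg.plants_path, cfg.meta_path)
    hoppers = cdio.read_community(cfg.hoppers_path, cfg.meta_path)
    env = cdio.read_blocks(cfg.blocks_dir, cfg.blockmap_path)
    return StudyData(env, plants, hoppers)


def preprocess_communities(cfg: PipelineConfig, data: StudyData):
    """Rarity-filter then transform each community (cover → log, counts →
    Hellinger)."""
    plants = occupancy_filter(data.plants, cfg.min_sites)
    hoppers = occupancy_filter(data.hoppers, cfg.min_sites)
    y_plants = log_transform_cover(plants, base=cfg.log_base)
    y_hoppers = hellinger_transform(hoppers)
    return plants, hoppers, y_plants, y_hoppers


# ---------------------------------------------------------------------------
# Step 1
# ---------------------------------------------------------------------------
def _select_blocks(cfg, Y, env: BlockCollection, tag: str) -> dict[str, list[str]]:
    keep: dict[str, list[str]] = {}
    for name, df in env.blocks.items():
        res = forward_select(
            Y,
            df.to_numpy(dtype=float),
            names=list(df.columns),
            alpha=cfg.alpha,
            n_perm=cfg.selection_n_perm,
            seed=child_seed(cfg.seed, f"fs:{tag}:{name}"),
        )
        if res.selected:
            keep[name] = res.selected
        else:
            logger.warning("block %s empty after selection for %s (%s); dropped",
                           name, tag, res.stop_reason)
    return keep


def run_step1_direction(cfg: PipelineConfig, Y: SiteSpeciesMatrix,
                        other: SiteSpeciesMatrix, env: BlockCollection,
                        tag: str) -> dict:
    """One direction of step 1 (focal community ~ abiotic blocks + biotic)."""
    Ymat = Y.values
    keep = _select_blocks(cfg, Ymat, env, tag)
    selected_env = env.subset(keep) if keep else None

    pls = plsr_fit(Ymat, other.values, h=2)
    biotic = pd.DataFrame(
        pls.scores,
        index=Y.site_ids,
        columns=[f"{tag}_pls1", f"{tag}_pls2"],
    )
    blocks = dict(selected_env.blocks) if selected_env else {}
    blocks["Biotic"] = biotic
    coll = BlockCollection(blocks)

    if cfg.h == "auto":
        h_max = min(cfg.h_max, _rank(coll))
        cv = select_ncomp_cv(
            Ymat, coll, h_max=h_max, folds=cfg.cv_folds,
            repeats=cfg.cv_repeats, seed=child_seed(cfg.seed, f"cv:{tag}"),
        )
        H = cv.h_best
    else:
        H = int(cfg.h)
        cv = None
    model = mbra_fit(Ymat, coll, H)
    bi = block_importance(model)
    vi = variable_importance(model)
    ti = bootstrap_intervals(
        Ymat, coll, H, B=cfg.bootstrap_b, level=cfg.interval_level,
        seed=child_seed(cfg.seed, f"boot:{tag}"),
    )
    return {
        "selected": keep,
        "pls_explained": pls.explained,
        "biotic_scores": biotic,
        "blocks": coll,
        "cv": cv,
        "model": model,
        "block_importance": bi,
        "variable_importance": vi,
        "intervals": ti,
    }


def _rank(coll: BlockCollection) -> int:
    X = coll.concat().to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    return int(np.linalg.matrix_rank(Xc, tol=1e-10 * max(1.0, np.abs(Xc).max())))


# ---------------------------------------------------------------------------
# Step 2 / Step 3
# ---------------------------------------------------------------------------
def run_step2_direction(cfg, Y: SiteSpeciesMatrix, step1: dict, tag: str):
    sel = step1["selected"]
    if not sel:
        raise StepFailureError(f"step2[{tag}]: no selected abiotic variables")
    frames = [step1["blocks"].blocks[name] for name in sel
              if name in step1["blocks"].blocks]
    Xa = pd.concat(frames, axis=1).to_numpy(dtype=float)
    Xb = step1["biotic_scores"].to_numpy(dtype=float)
    return varpart2(Y.values, Xa, Xb, n_perm=cfg.varpart_n_perm,
                    seed=child_seed(cfg.seed, f"vp:{tag}"))


def _chain_params(cfg: PipelineConfig, occ) -> tuple[int, int]:
    """Burn-in and thinning for one matrix.

    The sequential-swap chain needs attempts proportional to the number of
    cells to decorrelate; with ``adaptive_chain`` the configured values act
    as floors of 10x and 1x the cell count respectively."""
    if not cfg.adaptive_chain:
        return cfg.burn_in, cfg.thin
    cells = occ.n_species * occ.n_sites
    return max(cfg.burn_in, 10 * cells), max(cfg.thin, cells)


def run_step3(cfg: PipelineConfig, plants: SiteSpeciesMatrix,
              hoppers: SiteSpeciesMatrix) -> dict:
    occ_p = to_presence_absence(plants)
    occ_h = to_presence_absence(hoppers)
    out: dict = {}
    for name, occ in (("plants", occ_p), ("leafhoppers", occ_h)):
        burn_in, thin = _chain_params(cfg, occ)
        ens = ff_swap_null(occ, n_null=cfg.n_null, burn_in=burn_in,
                           thin=thin,
                           seed=child_seed(cfg.seed, f"ff:{name}"))
        out[f"matrix_level_{name}"] = matrix_level_test(occ, ens)

    meta = pd.concat([plants.meta, hoppers.meta])
    pm = build_pair_matrices(
        occ_p, occ_h, meta,
        common_rule=CommonPlantRule(top_n=cfg.common_top_n),
        abundance=plants.data,
    )
    out["unmatched_specialists"] = pm.unmatched
    for label, occ in (("gc", pm.gc), ("sh", pm.sh)):
        if occ is None or occ.n_species < 2:
            out[f"pairs_{label}"] = []
            continue
        burn_in, thin = _chain_params(cfg, occ)
        ens = ff_swap_null(occ, n_null=cfg.n_null, burn_in=burn_in,
                           thin=thin,
                           seed=child_seed(cfg.seed, f"ff:{label}"))
        pairs = pairwise_test(occ, ens, level=cfg.cl_level)
        bayes_m_filter(pairs, ens, n_bins=cfg.n_bins)
        out[f"pairs_{label}"] = pairs
        out[f"table_cl_{label}"] = classify_pairs(pairs, criterion="cl")
        out[f"table_bayesm_{label}"] = classify_pairs(pairs, criterion="bayesm")
    return out


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------
def run_all(cfg: PipelineConfig) -> dict:
    """Execute steps 1–3 and return (and optionally persist) the run report."""
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
    }

    def _persist():
        if out_dir:
            cdio.write_json(report, out_dir / "report.json")

    try:
        data = load_data(cfg)
        plants, hoppers, y_plants, y_hoppers = preprocess_communities(cfg, data)
        report["n_sites"] = plants.n_sites
        report["n_plants_retained"] = plants.n_species
        report["n_hoppers_retained"] = hoppers.n_species
    except Exception as exc:  # noqa: BLE001
        _persist()
        raise StepFailureError(f"preprocess: {exc}") from exc

    step1 = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            step1["plants"] = run_step1_direction(
                cfg, y_plants, y_hoppers, data.env, "plants")
            step1["leafhoppers"] = run_step1_direction(
                cfg, y_hoppers, y_plants, data.env, "leafhoppers")
        for tag, res in step1.items():
            report[f"step1_{tag}"] = _step1_report(res)
            if out_dir:
                _write_step1(res, out_dir, tag)
    except StepFailureError:
        raise
    except Exception as exc:  # noqa: BLE001
        _persist()
        raise StepFailureError(f"step1: {exc}") from exc

    try:
        for tag, Y in (("plants", y_plants), ("leafhoppers", y_hoppers)):
            vp = run_step2_direction(cfg, Y, step1[tag], tag)
            report[f"step2_{tag}"] = summarize_varpart(vp)
            report[f"step2_{tag}"]["fractions"] = {
                "a": vp.fraction_a, "b": vp.fraction_b,
                "c": vp.fraction_c, "d": vp.fraction_d,
            }
    except StepFailureError:
        raise
    except Exception as exc:  # noqa: BLE001
        _persist()
        raise StepFailureError(f"step2: {exc}") from exc

    try:
        step3 = run_step3(cfg, plants, hoppers)
        for name in ("plants", "leafhoppers"):
            r = step3[f"matrix_level_{name}"]
            report[f"step3_matrix_{name}"] = {
                "observed": r.observed, "null_mean": r.null_mean,
                "ses": r.ses, "p_upper": r.p_upper, "p_lower": r.p_lower,
            }
        for label in ("gc", "sh"):
            pairs = step3[f"pairs_{label}"]
            n_cl = sum(p.cl_flag for p in pairs)
            n_bm = sum(p.bayesm_flag for p in pairs)
            entry = {
                "n_pairs": len(pairs),
                "n_cl_flagged": n_cl,
                "n_bayesm_flagged": n_bm,
                "n_segregated": sum(
                    p.classification == "segregated" and p.cl_flag for p in pairs),
                "n_aggregated": sum(
                    p.classification == "aggregated" and p.cl_flag for p in pairs),
            }
            if f"table_cl_{label}" in step3:
                entry["table_cl"] = step3[f"table_cl_{label}"].to_dict()
                entry["table_bayesm"] = step3[f"table_bayesm_{label}"].to_dict()
            report[f"step3_pairs_{label}"] = entry
            if out_dir and pairs:
                pairs_to_frame(pairs).to_csv(
                    out_dir / f"pairs_{label}.tsv", sep="\t", index=False)
        report["step3_unmatched_specialists"] = step3["unmatched_specialists"]
    except StepFailureError:
        raise
    except Exception as exc:  # noqa: BLE001
        _persist()
        raise StepFailureError(f"step3: {exc}") from exc

    _persist()
    return report


def _step1_report(res: dict) -> dict:
    model = res["model"]
    bi = res["block_importance"]
    vi = res["variable_importance"]
    return {
        "selected": res["selected"],
        "pls_explained_pct": [round(float(x), 1) for x in res["pls_explained"]],
        "H": model.H,
        "lambda_per_dim": model.lambdas.tolist(),
        "y_explained_cum": model.y_explained.tolist(),
        "block_explained_final": dict(
            zip(model.block_names, model.block_explained[:, -1].tolist())
        ),
        "block_importance": dict(zip(bi.labels, bi.values.tolist())),
        "block_threshold": bi.threshold,
        "blocks_flagged": bi.flagged,
        "variable_importance": dict(zip(vi.labels, vi.values.tolist())),
        "variable_threshold": vi.threshold,
        "variables_flagged": vi.flagged,
    }


def _write_step1(res: dict, out_dir: Path, tag: str) -> None:
    model = res["model"]
    cdio.write_json(
        {
            "H": model.H,
            "lambdas": model.lambdas,
            "a": model.a,
            "block_names": model.block_names,
            "var_labels": model.var_labels,
            "y_explained": model.y_explained,
            "block_explained": model.block_explained,
        },
        out_dir / f"model_{tag}.json",
    )
    bi, vi, ti = (res["block_importance"], res["variable_importance"],
                  res["intervals"])
    rows = [
        {"index": "block", "label": lab, "value": val, "lo": lo, "hi": hi,
         "flag": val > bi.threshold}
        for lab, val, lo, hi in zip(bi.labels, bi.values, ti.block_lo, ti.block_hi)
    ] + [
        {"index": "variable", "label": lab, "value": val, "lo": lo, "hi": hi,
         "flag": val > vi.threshold}
        for lab, val, lo, hi in zip(vi.labels, vi.values, ti.var_lo, ti.var_hi)
    ]
    pd.DataFrame(rows).to_csv(out_dir / f"importance_{tag}.tsv", sep="\t",
                              index=False)
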