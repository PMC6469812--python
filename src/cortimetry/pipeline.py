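"""Reproducible pipeline orchestration: simulate -> segment -> morph -> stats.

A run takes a single YAML-style configuration (every stage block optional,
defaults reproducing the standard processing constants), executes the
stages in order, and writes all artifacts plus a manifest with the fully
resolved configuration and a SHA-256 hash of every output file. Re-running
with the same configuration and seed reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as cio
from . import morphometry, stats, synthetic
from .segmentation import SegmentationConfig, segment_section

__all__ = ["default_config", "resolve_config", "run_pipeline", "PipelineError"]

log = logging.getLogger("cortimetry")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def default_config() -> dict:
    return {
        "seed": 0,
        "simulate": {
            "n_subjects": 5,
            "morphometry_mode": "image",
        },
        "segmentation": dataclasses.asdict(SegmentationConfig()),
        "morphometry": {
            "thresholds_um": list(morphometry.THRESHOLDS_UM),
            "bin_width_px": 1.0,
        },
        "roi": {"sector_center_deg": None, "sector_width_deg": 60.0},
        "stats": {
            "covariate": "aBMD_neck_left",
            "outcomes": [f"{c}_left" for c in synthetic.OUTCOME_COLUMNS],
            "alpha": 0.05,
        },
        "inputs": None,  # list of {image, endosteal} paths for real sections
    }


def _merge(base: dict, override: Optional[dict]) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def resolve_config(config: Optional[dict] = None, seed: Optional[int] = None) -> dict:
    cfg = _merge(default_config(), config)
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _segment_and_measure(img, endo_contour, cfg, name: str):
    try:
        seg_cfg = SegmentationConfig(**cfg["segmentation"])
        masks, prov = segment_section(img, endo_contour, seg_cfg)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage 'segment' failed on {name}: {e}") from e
    try:
        rec, pores = morphometry.analyze_section(
            masks,
            img,
            thresholds_um=tuple(cfg["morphometry"]["thresholds_um"]),
            bin_width_px=cfg["morphometry"]["bin_width_px"],
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage 'morph' failed on {name}: {e}") from e
    return masks, prov, rec, pores


def run_pipeline(config: Optional[dict] = None, out_dir: str | Path = "run",
                 seed: Optional[int] = None) -> Path:
    """Execute the configured pipeline and write a manifest.

    Synthetic mode (``inputs`` unset) simulates a cohort, segments and
    measures every generated section through the full image chain, plants
    the outcomes, and runs the association stage. With ``inputs`` set, the
    listed real images are segmented and measured instead (no outcome or
    statistics stage unless a cohort CSV is supplied separately).
    """
    cfg = resolve_config(config, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if cfg["inputs"]:
        records = []
        for item in cfg["inputs"]:
            img_path = Path(item["image"])
            endo_path = Path(item.get("endosteal", ""))
            if not img_path.exists():
                raise PipelineError(f"stage 'segment': missing image file {img_path}")
            if not endo_path.exists():
                raise PipelineError(
                    f"stage 'segment': missing endosteal input {endo_path} "
                    f"for image {img_path}"
                )
            img = cio.read_image(img_path)
            endo = cio.read_contour_csv(endo_path)
            masks, prov, rec, pores = _segment_and_measure(img, endo, cfg, img_path.name)
            rec["section"] = img_path.stem
            records.append(rec)
            written.append(cio.write_mask_png(masks.cortical_mask,
                                              out / f"{img_path.stem}_cortical.png"))
            pores.to_csv(out / f"{img_path.stem}_pores.csv", index=False)
            written.append(out / f"{img_path.stem}_pores.csv")
        morpho = pd.DataFrame(records)
        morpho.to_csv(out / "morphometry.csv", index=False)
        written.append(out / "morphometry.csv")
    else:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", cfg["seed"])
        try:
            cspec = synthetic.CohortSpec(**sim)
            cohort, truths = synthetic.generate_cohort(cspec)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage 'simulate' failed: {e}") from e
        cohort.to_csv(out / "cohort.csv", index=False)
        written.append(out / "cohort.csv")
        morpho_cols = ["subject"] + morphometry.MORPHOMETRY_COLUMNS
        cohort[morpho_cols].to_csv(out / "morphometry.csv", index=False)
        written.append(out / "morphometry.csv")
        try:
            st = cfg["stats"]
            table = stats.build_association_table(
                cohort,
                covariate=st["covariate"],
                outcomes=st["outcomes"],
                predictors=morphometry.MORPHOMETRY_COLUMNS,
                alpha=st["alpha"],
            )
            table.to_csv(out / "associations.csv", index=False)
            written.append(out / "associations.csv")
            models = []
            for y in st["outcomes"]:
                base = stats.fit_linear_model(
                    cohort[y], cohort[[st["covariate"]]], response_name=y
                )
                full = stats.fit_linear_model(
                    cohort[y],
                    cohort[[st["covariate"], "relCt.Po_100"]],
                    response_name=y,
                )
                models.append(
                    {
                        "response": y,
                        "adj_r2_covariate_only": base.adj_r2,
                        "adj_r2_with_large_pores": full.adj_r2,
                        "beta_covariate": full.betas[st["covariate"]],
                        "beta_relCt.Po_100": full.betas["relCt.Po_100"],
                        "p_relCt.Po_100": full.pvalues["relCt.Po_100"],
                    }
                )
            pd.DataFrame(models).to_csv(out / "models.csv", index=False)
            written.append(out / "models.csv")
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"stage 'stats' failed: {e}") from e

    manifest = {
        "config": cfg,
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=repr)
    )
    log.info("pipeline run complete: %d artifacts in %s", len(written), out)
    return out
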