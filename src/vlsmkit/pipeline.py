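"""End-to-end orchestration: simulate/load, lesions, phenotypes, stats, maps.

One call produces a self-contained artifact directory: dysfunction masks,
coverage map, phenotype table, association statistics, one corrected map
per phenotype, the overlap summary, and a JSON provenance record with every
effective parameter, the seed, and the patient counts at each filter.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .behavior import BehaviorRecord, derive_phenotypes, phenotypes_to_frame
from .compare import compare_maps
from .io import CohortImages, read_cohort_from_manifest, save_volume, write_stat_map
from .lesions import build_dysfunction_masks, coverage_map
from .simulate import SimConfig, simulate_cohort, write_cohort
from .stats import TwoByTwo, ancova_group_comparison, chi_square
from .vlsm import VlsmConfig, run_vlsm

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full study run needs."""

    out_dir: str
    manifest: Optional[str] = None
    behavior: Optional[str] = None
    simulate: bool = True
    sim_config: SimConfig = field(default_factory=SimConfig)
    vlsm_config: VlsmConfig = field(default_factory=VlsmConfig)
    phenotypes: tuple[str, ...] = ("aos", "span")
    ttp_threshold_s: float = 4.0
    seed: int = 0


def _association_stats(phen_frame: pd.DataFrame, lesion_volumes: np.ndarray) -> dict:
    """Chi-square AOS x span-impairment and the lesion-adjusted span ANCOVA."""
    out: dict = {}
    df = phen_frame.copy()
    df["lesion_volume"] = lesion_volumes
    det = df[df.aos_status != "indeterminate"].dropna(subset=["span_impaired"])
    if len(det):
        aos = det.aos_status == "AOS"
        imp = det.span_impaired.astype(bool)
        table = TwoByTwo(
            int((aos & imp).sum()), int((aos & ~imp).sum()),
            int((~aos & imp).sum()), int((~aos & ~imp).sum()),
        )
        try:
            stat, p = chi_square(table)
            out["chi_square_aos_vstm"] = {
                "statistic": stat, "p": p,
                "table": [table.a, table.b, table.c, table.d],
            }
        except ValueError as exc:
            out["chi_square_aos_vstm"] = {"error": str(exc)}
    span_det = det.dropna(subset=["digit_span"])
    if len(span_det) and span_det.aos_status.nunique() == 2:
        res = ancova_group_comparison(
            span_det.digit_span.to_numpy(float),
            (span_det.aos_status == "AOS").to_numpy(int),
            span_det.lesion_volume.to_numpy(float),
        )
        out["ancova_span_by_aos"] = {
            "f_statistic": res.f_statistic,
            "df": list(res.df),
            "p": res.p_value,
            "adjusted_mean_no_aos": res.adjusted_means[0],
            "adjusted_mean_aos": res.adjusted_means[1],
            "slope": res.slope,
        }
    return out


def run_full_study(cfg: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``cfg.out_dir``.

    Returns the provenance record (also written as ``provenance.json``).
    Any stage failure raises with the stage named.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    prov: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "phenotypes": list(cfg.phenotypes),
        "ttp_threshold_s": cfg.ttp_threshold_s,
        "vlsm_config": asdict(cfg.vlsm_config),
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        name = stage("cohort")
        if cfg.simulate:
            sim = cfg.sim_config
            sim = SimConfig(**{**asdict_sim(sim), "seed": cfg.seed})
            cohort, records, truth = simulate_cohort(sim)
            data_dir = os.path.join(cfg.out_dir, "cohort")
            write_cohort(data_dir, cohort, records, truth)
            prov["stages"][name] = {"simulated": True, "n_patients": cohort.n_patients}
        else:
            if cfg.manifest is None or cfg.behavior is None:
                raise ValueError("manifest and behavior paths required when not simulating")
            cohort, records = read_cohort_from_manifest(cfg.manifest, cfg.behavior)
            prov["stages"][name] = {"simulated": False, "n_patients": cohort.n_patients}

        name = stage("lesions")
        masks = build_dysfunction_masks(cohort, cfg.ttp_threshold_s)
        cov = coverage_map(masks)
        save_volume(cov, cohort.grid, os.path.join(cfg.out_dir, "coverage.nii.gz"))
        pd.DataFrame(
            {"patient_id": masks.patient_ids, "lesion_volume": masks.lesion_volumes}
        ).to_csv(os.path.join(cfg.out_dir, "lesion_volumes.tsv"), sep="\t", index=False)
        prov["stages"][name] = {
            "total_lesioned_voxels": int(masks.lesion_volumes.sum()),
            "max_coverage": int(cov.max()),
        }

        name = stage("phenotype")
        phen = derive_phenotypes(records)
        phen_frame = phenotypes_to_frame(phen)
        phen_frame.to_csv(os.path.join(cfg.out_dir, "phenotypes.tsv"), sep="\t", index=False)
        prov["stages"][name] = {
            "n_aos": int((phen_frame.aos_status == "AOS").sum()),
            "n_no_aos": int((phen_frame.aos_status == "no_AOS").sum()),
            "n_indeterminate": int((phen_frame.aos_status == "indeterminate").sum()),
            "n_span_impaired": int(phen_frame.span_impaired.fillna(False).sum()),
        }

        name = stage("assoc")
        assoc = _association_stats(phen_frame, masks.lesion_volumes)
        with open(os.path.join(cfg.out_dir, "associations.json"), "w") as fh:
            json.dump(assoc, fh, indent=2)
        prov["stages"][name] = {k: True for k in assoc}

        name = stage("vlsm")
        sig_masks = {}
        for ph in cfg.phenotypes:
            result = run_vlsm(cohort, records, ph, cfg.vlsm_config, masks=masks)
            stem = os.path.join(cfg.out_dir, f"vlsm_{ph}")
            write_stat_map(result.stat_map, stem)
            save_volume(result.clusters.labels.astype(np.int32), cohort.grid,
                        stem + "_clusters.nii.gz")
            sig = result.clusters.significant_mask
            save_volume(sig, cohort.grid, stem + "_significant.nii.gz")
            pd.DataFrame(
                [
                    {
                        "label": lab,
                        "n_voxels": sz,
                        "significant": lab in result.clusters.significant_labels,
                    }
                    for lab, sz in sorted(result.clusters.cluster_sizes.items())
                ]
            ).to_csv(stem + "_clusters.tsv", sep="\t", index=False)
            prov["stages"][f"vlsm_{ph}"] = result.provenance
            sig_masks[ph] = sig

        if len(sig_masks) == 2:
            name = stage("compare")
            m1, m2 = (sig_masks[p] for p in cfg.phenotypes)
            summary = compare_maps(m1, m2)
            for suffix, m in (
                ("overlap", summary.overlap_mask),
                (f"unique_{cfg.phenotypes[0]}", summary.unique1_mask),
                (f"unique_{cfg.phenotypes[1]}", summary.unique2_mask),
            ):
                save_volume(m, cohort.grid, os.path.join(cfg.out_dir, f"compare_{suffix}.nii.gz"))
            cmp_record = {
                "n_voxels_map1": summary.n_voxels_map1,
                "n_voxels_map2": summary.n_voxels_map2,
                "n_overlap": summary.n_overlap,
                "dice": summary.dice,
            }
            with open(os.path.join(cfg.out_dir, "compare.json"), "w") as fh:
                json.dump(cmp_record, fh, indent=2)
            prov["stages"][name] = cmp_record
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    with open(os.path.join(cfg.out_dir, "provenance.json"), "w") as fh:
        json.dump(prov, fh, indent=2)
    return prov


def asdict_sim(sim: SimConfig) -> dict:
    """SimConfig -> kwargs dict, keeping region arrays by reference."""
    return {
        "grid_shape": sim.grid_shape,
        "n_patients": sim.n_patients,
        "lesion_size_range": sim.lesion_size_range,
        "hypoperfusion_halo_p": sim.hypoperfusion_halo_p,
        "critical_regions": sim.critical_regions,
        "deficit_models": sim.deficit_models,
        "ttp_base_s": sim.ttp_base_s,
        "ttp_delay_s": sim.ttp_delay_s,
        "midline_axis": sim.midline_axis,
        "seed": sim.seed,
    }
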