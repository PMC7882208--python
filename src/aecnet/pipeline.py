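"""End-to-end orchestration: simulate → reject → connect → NBS → behaviour.

``run_pipeline`` is a pure function of (config, seed): every stochastic
stage consumes a named seed derived from the master seed, provenance
(config hash, seeds) is embedded in each output, and running twice with
the same config yields byte-identical JSON results.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import brainbehav, connectivity, nbs, preprocess, synthgen
from .io import PipelineConfig, derive_seeds, make_demo_atlas, write_atlas, write_brainnet

logger = logging.getLogger(__name__)

STAGES = ("simulate", "behaviour", "nbs")


def _window_key(w) -> str:
    return f"{w[0]:g}-{w[1]:g}s"


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis on a synthetic dataset and write artifacts.

    Writes atlas.tsv, rejection.tsv, per-(band, window) AEC TSVs for the
    group means, nbs.json, models.tsv, .node/.edge files for significant
    components, and report.md. Returns the results dict (also serialised
    to nbs.json / results.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed, STAGES)

    atlas = make_demo_atlas(config.n_nodes)
    write_atlas(atlas, out / "atlas.tsv")

    spec = synthgen.SyntheticSpec(
        n_nodes=config.n_nodes,
        n_subjects_per_group=config.n_subjects_per_group,
        n_trials=config.n_trials,
        fs=config.fs,
        band=config.band,
        planted_edges=config.planted_edges,
        coupling_by_group=config.coupling_by_group,
        baseline_coupling=config.baseline_coupling,
        mixing_strength=config.mixing_strength,
        artefact_rates=config.artefact_rates,
        seed=seeds["simulate"],
    )
    try:
        subjects, truth = synthgen.generate_source_dataset(spec)
    except ValueError as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # trial rejection (amplitude criterion; source tier has no fiducials)
    rejection_rows = []
    for s in subjects:
        s.epochs = preprocess.reject_amplitude(s.epochs, config.amp_threshold_ft)
        rep = preprocess.rejection_report(s.epochs)
        rep.insert(0, "subject", s.subject_id)
        rejection_rows.append(rep)
    pd.concat(rejection_rows).to_csv(out / "rejection.tsv", sep="\t", index=False)

    # connectivity per subject, analysed band only (configurable list)
    bands = [config.band] if config.band else list(config.bands)
    samples = {}
    aec_by_subject = {}
    for s in subjects:
        try:
            res = connectivity.aec_pipeline(
                s.epochs, bands=bands, condition="Social", eps=config.eps
            )
        except ValueError as exc:
            raise RuntimeError(
                f"stage 'connectivity' failed for subject {s.subject_id}: {exc}"
            ) from exc
        aec_by_subject[s.subject_id] = res
    groups = sorted({s.group for s in subjects})
    for band in bands:
        for w in connectivity.TASK_WINDOWS:
            mats = {
                g: np.stack(
                    [
                        aec_by_subject[s.subject_id].baselined[band][w]
                        for s in subjects
                        if s.group == g
                    ]
                )
                for g in groups
            }
            samples[(band, w)] = (mats[groups[0]], mats[groups[1]])
            mean_mat = np.stack([m.mean(axis=0) for m in mats.values()]).mean(axis=0)
            np.savetxt(
                out / f"aec_{band}_{_window_key(w)}.tsv",
                mean_mat,
                fmt="%.6g",
                delimiter="\t",
                header="\t".join(atlas["label"]),
                comments="",
            )

    try:
        nbs_results = nbs.run_all(
            samples, tau=config.tau, n_perm=config.n_perm, seed=seeds["nbs"]
        )
    except ValueError as exc:
        raise RuntimeError(f"stage 'nbs' failed: {exc}") from exc

    results = {
        "provenance": {
            "config_hash": config.hash(),
            "seeds": seeds,
            "config": config.to_dict(),
        },
        "networks": [],
    }
    sig = []
    for (band, w, direction), r in sorted(nbs_results.items(), key=lambda kv: str(kv[0])):
        for ci, c in enumerate(r.components):
            entry = {
                "band": band,
                "window": list(w),
                "direction": direction,
                "extent": c.extent,
                "p_fwe": c.p_fwe,
                "edges": [list(e) for e in c.edges],
                "tau": r.tau,
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
            results["networks"].append(entry)
            if c.p_fwe <= 0.05:
                sig.append((band, w, direction, c))
                write_brainnet(
                    c,
                    atlas,
                    out / f"net_{band}_{_window_key(w)}_{direction}_{ci}.node",
                    out / f"net_{band}_{_window_key(w)}_{direction}_{ci}.edge",
                )

    # brain-behaviour on significant networks (raw task AEC, per the
    # node-strength definition)
    model_rows = []
    if sig:
        rng_seed = seeds["behaviour"]
        records = []
        for band, w, direction, comp in sig:
            strengths = []
            grp = []
            sids = []
            for s in subjects:
                mat = aec_by_subject[s.subject_id].raw[band][w]
                _, mean_strength = brainbehav.node_strength(mat, comp.edges)
                strengths.append(mean_strength)
                grp.append(s.group)
                sids.append(s.subject_id)
            counts = synthgen.generate_behaviour(
                np.asarray(strengths),
                grp,
                slope_by_group=config.behaviour_slopes,
                noise_sd=config.behaviour_noise_sd,
                seed=rng_seed,
            )
            records.append(
                pd.DataFrame(
                    {
                        "subject": sids,
                        "group": grp,
                        "strength": strengths,
                        "errors": counts,
                        "network": f"{band}_{_window_key(w)}_{direction}",
                        "band": band,
                    }
                )
            )
        table = pd.concat(records, ignore_index=True)
        models = brainbehav.strength_glm(table, error_type="simulated")
        models.to_csv(out / "models.tsv", sep="\t", index=False)
        model_rows = models.to_dict("records")
    results["models"] = model_rows

    with open(out / "results.json", "w") as f:
        json.dump(results, f, indent=2, sort_keys=True)
    _write_report(out, config, subjects, truth, results)
    return results


def _write_report(out: Path, config, subjects, truth, results) -> None:
    n_rej = sum(int((~s.epochs.kept).sum()) for s in subjects)
    n_tot = sum(s.epochs.n_trials for s in subjects)
    lines = [
        "# Pipeline run report",
        "",
        f"- config hash: `{results['provenance']['config_hash']}`",
        f"- subjects: {len(subjects)} ({config.n_subjects_per_group}/group)",
        f"- trials rejected: {n_rej} of {n_tot}",
        f"- planted edges: {list(truth.planted_edges)}",
        f"- networks found: {len(results['networks'])} "
        f"(significant: {sum(1 for n in results['networks'] if n['p_fwe'] <= 0.05)})",
        "",
        "| band | window | direction | extent | p_FWE |",
        "|------|--------|-----------|--------|-------|",
    ]
    for n in results["networks"]:
        lines.append(
            f"| {n['band']} | {n['window'][0]:g}-{n['window'][1]:g} s | "
            f"{n['direction']} | {n['extent']} | {n['p_fwe']:.4g} |"
        )
    if results.get("models"):
        lines += ["", "| network | band | beta | p | q |", "|---|---|---|---|---|"]
        for m in results["models"]:
            lines.append(
                f"| {m['network']} | {m['band']} | {m['beta']:.4g} | "
                f"{m['p']:.4g} | {m['q']:.4g} |"
            )
    (out / "report.md").write_text("\n".join(lines) + "\n")
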