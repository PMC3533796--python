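"""One-config orchestration of the full analysis, with a manifest.

Stage order: input (sync or synthetic) -> masking -> SNP calling -> CMH
scans -> neutral null simulation -> empirical FDR -> candidates and
trajectories -> Ne estimation -> (optional) enrichment.  Each stage writes
its outputs into the result directory; a completed stage whose outputs
already exist is skipped unless ``force``.  The manifest records the seed,
the config digest, and a content digest plus row count for every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drift, ne, snp_calling, sync_io, trajectories
from .cmh import cmh_scan
from .design import ExperimentDesign, default_design
from .synth import SelectionModel, generate_experiment

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "validate_design"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _parse_planted(spec_list) -> list[tuple[int, SelectionModel]]:
    out = []
    for entry in spec_list or []:
        idx = int(entry["locus"])
        kw = {k: v for k, v in entry.items() if k != "locus"}
        out.append((idx, SelectionModel(**kw)))
    return out


def validate_design(design_path: str | Path) -> str:
    """Validate a design file; returns the human-readable structure report."""
    design = ExperimentDesign.from_yaml(design_path)  # raises DesignError
    return design.describe()


class _Runner:
    def __init__(self, config: dict, outdir: Path, force: bool):
        self.cfg = config
        self.out = outdir
        self.force = force
        self.seed = int(config.get("seed", 0))
        self.manifest: dict = {"seed": self.seed, "stages": {}, "outputs": {}}
        payload = json.dumps(config, sort_keys=True, default=str)
        self.manifest["config_digest"] = hashlib.sha256(payload.encode()).hexdigest()[:12]

    def done(self, *paths: Path) -> bool:
        return not self.force and all(p.exists() for p in paths)

    def record(self, stage: str, *paths: Path, rows: int | None = None,
               cached: bool = False) -> None:
        self.manifest["stages"][stage] = {"outputs": [p.name for p in paths],
                                          "rows": rows, "cached": cached}
        for p in paths:
            self.manifest["outputs"][p.name] = _sha256(p)
        log.info("stage %s%s: %s (%s rows)", stage, " [cached]" if cached else "",
                 [p.name for p in paths], rows)


def run_pipeline(config_path: str | Path, outdir: str | Path, force: bool = False) -> Path:
    """Execute the configured analysis end to end; returns the result dir."""
    cfg = yaml.safe_load(Path(config_path).read_text())
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    r = _Runner(cfg, out, force)
    seed = r.seed

    # -- design ------------------------------------------------------------
    if "design" in cfg and isinstance(cfg["design"], str):
        design = ExperimentDesign.from_yaml(Path(config_path).parent / cfg["design"])
    elif "design" in cfg:
        design = ExperimentDesign.from_dict(cfg["design"])
    else:
        design = default_design()

    # -- input -------------------------------------------------------------
    snps_path = out / "snps.tsv"
    call_cfg = cfg.get("snp_calling", {})
    if not r.done(snps_path):
        if "synthetic" in cfg:
            syn_cfg = dict(cfg["synthetic"])
            planted = _parse_planted(syn_cfg.pop("planted", None))
            exp = generate_experiment(design=design, seed=seed, planted=planted, **syn_cfg)
            exp.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            records = exp.to_sync_records()
        else:
            sync_file = Path(cfg["input"]["sync"])
            records = sync_io.read_sync(sync_file, design.n_populations)
        masks_cfg = cfg.get("masks", {})
        masks = sync_io.MaskSet()
        if masks_cfg.get("exclude_bed"):
            masks.update(sync_io.MaskSet.from_bed(masks_cfg["exclude_bed"]))
        if masks_cfg.get("repeats_gff"):
            masks.update(sync_io.MaskSet.from_gff(masks_cfg["repeats_gff"]))
        if masks_cfg.get("indels_tsv"):
            calls = []
            with open(masks_cfg["indels_tsv"]) as fh:
                for line in fh:
                    f = line.split("\t")
                    if len(f) >= 4:
                        calls.append((f[0], int(f[1]), f[2], int(f[3])))
            masks.update(sync_io.build_indel_mask(calls,
                                                  flank=int(masks_cfg.get("flank", 5)),
                                                  min_reads=int(masks_cfg.get("min_indel_reads", 2))))
        if len(masks):
            records = sync_io.apply_masks(records, masks)
        table = snp_calling.call_snp_table(records, design.population_names, **call_cfg)
        table.write_tsv(snps_path)
        r.record("call_snps", snps_path, rows=len(table))
    else:
        r.record("call_snps", snps_path, cached=True)
    snps = snp_calling.SnpTable.read_tsv(snps_path)

    # -- CMH scans -----------------------------------------------------------
    contrasts = [tuple(c) for c in cfg.get("contrasts", [["B", "M"], ["B", "E"], ["M", "E"]])]
    scans: dict[str, pd.DataFrame] = {}
    for t0, t1 in contrasts:
        path = out / f"cmh_{t0}{t1}.tsv"
        if not r.done(path):
            frame = cmh_scan(snps, design, (t0, t1))
            frame.to_csv(path, sep="\t", index=False)
            r.record(f"cmh_{t0}-{t1}", path, rows=len(frame))
        else:
            r.record(f"cmh_{t0}-{t1}", path, cached=True)
        scans[f"{t0}-{t1}"] = pd.read_csv(path, sep="\t", dtype={"chrom": str})

    # -- null simulation + FDR ---------------------------------------------
    null_cfg = cfg.get("null", {})
    config = drift.SimulationConfig(
        ne=float(null_cfg.get("ne", design.ne)),
        seed=seed + 1,
        coverage_model=tuple(null_cfg.get("coverage_model", ("matched",))),
    )
    fdr_rows = []
    sim_scans: dict[str, pd.DataFrame] = {}
    for t0, t1 in contrasts:
        key = f"{t0}-{t1}"
        path = out / f"sim_pvalues_{t0}{t1}.tsv"
        if not r.done(path):
            _, sims = drift.simulate_null_experiment(snps, design, config, contrasts=[(t0, t1)])
            frame = sims[key]
            with open(path, "w") as fh:
                fh.write(f"# seed={config.seed} config={config.digest()}\n")
                frame.to_csv(fh, sep="\t", index=False)
            r.record(f"null_{key}", path, rows=len(frame))
        else:
            r.record(f"null_{key}", path, cached=True)
        sim_scans[key] = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        exp_p = scans[key]["p_value"].to_numpy()
        sim_p = sim_scans[key]["p_value"].to_numpy()
        thr = drift.empirical_threshold(sim_p, float(cfg.get("fdr", {}).get("top_fraction", 1e-5)))
        res = drift.empirical_fdr(exp_p, sim_p, thr)
        fdr_rows.append({"contrast": key, "mode": "top_fraction", **res.__dict__})
        top_n = int(cfg.get("fdr", {}).get("top_n", 2000))
        n_def = int(np.sum(~np.isnan(exp_p)))
        if n_def >= top_n:
            res2 = drift.fdr_top_n(exp_p, sim_p, top_n)
            fdr_rows.append({"contrast": key, "mode": f"top_{top_n}", **res2.__dict__})
    fdr_path = out / "fdr.tsv"
    pd.DataFrame(fdr_rows).to_csv(fdr_path, sep="\t", index=False)
    r.record("fdr", fdr_path, rows=len(fdr_rows))

    # -- candidates and trajectories ----------------------------------------
    n_top = int(cfg.get("candidates", {}).get("n", 2000))
    cand_sets = {}
    for key, frame in scans.items():
        n_def = frame["p_value"].notna().sum()
        use_n = min(n_top, int(n_def))
        if use_n == 0:
            continue
        cand = trajectories.top_candidates(frame, use_n)
        cand_sets[key] = cand
        cpath = out / f"candidates_{key.replace('-', '')}.tsv"
        cand.table.to_csv(cpath, sep="\t", index=False)
        r.record(f"candidates_{key}", cpath, rows=len(cand.table))

    primary = cfg.get("trajectory_contrast", ["B", "E"])
    key = f"{primary[0]}-{primary[1]}"
    if key in cand_sets:
        is_minor, _flag = trajectories.orient_selected_allele(snps, design, tuple(primary))
        traj = trajectories.trajectory_table(snps, design, is_minor)
        tpath = out / "trajectories.tsv"
        traj.to_csv(tpath, sep="\t", index=False)
        r.record("trajectories", tpath, rows=len(traj))
        if {"B-M", "M-E"} <= {f"{a}-{b}" for a, b in contrasts} | {key}:
            try:
                rise, _ = trajectories.interval_afc(snps, design, is_minor, "B", "M")
                late, _ = trajectories.interval_afc(snps, design, is_minor, "M", "E")
                ckeys = cand_sets[key].keys()
                in_cand = np.array([k in ckeys for k in snps.keys()])
                rise_min, flat_max = trajectories.auto_thresholds(
                    rise[in_cand], _null_late_afc(snps, design, config))
                labels = trajectories.classify_trajectories(rise[in_cand], late[in_cand],
                                                            rise_min, flat_max)
                cls = pd.DataFrame({
                    "chrom": snps.chrom[in_cand], "pos": snps.pos[in_cand],
                    "afc_BM": rise[in_cand], "afc_ME": late[in_cand], "label": labels,
                })
                cls.attrs["rise_min"] = rise_min
                cls.attrs["flat_max"] = flat_max
                lpath = out / "classification.tsv"
                cls.to_csv(lpath, sep="\t", index=False)
                r.record("classification", lpath, rows=len(cls))
            except Exception as exc:  # classification needs all of B/M/E
                log.warning("trajectory classification skipped: %s", exc)

    # -- Ne ------------------------------------------------------------------
    ne_cfg = cfg.get("ne_estimate", {})
    try:
        rngne = np.random.default_rng(seed + 2)
        report = ne.estimate_ne_from_table(
            snps, design, pair=tuple(ne_cfg.get("pair", ("B", "E"))),
            n_snps=int(ne_cfg.get("n_snps", 1000)) if len(snps) > 1000 else None,
            n_boot=int(ne_cfg.get("bootstrap", 200)), rng=rngne)
        npath = out / "ne_report.tsv"
        with open(npath, "w") as fh:
            fh.write("# moment-based temporal estimator (sampling plan II, two-stage Pool-Seq correction)\n")
            report.to_csv(fh, sep="\t", index=False)
        r.record("ne", npath, rows=len(report))
    except Exception as exc:
        log.warning("Ne estimation skipped: %s", exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(r.manifest, fh, indent=2, sort_keys=True)
    return out


def _null_late_afc(snps, design, config) -> np.ndarray:
    """Drift envelope of the late-phase AFC used by auto classification."""
    rng = np.random.default_rng(config.seed + 7)
    sim, _ = drift.simulate_null_experiment(snps, design, config, contrasts=[], rng=rng)
    freqs = sim.minor_freqs()
    changes = []
    for i0, i1, _rep, _t in design.contrast_pairs("M", "E"):
        changes.append(freqs[:, i1] - freqs[:, i0])
    return np.nanmean(np.column_stack(changes), axis=1)
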