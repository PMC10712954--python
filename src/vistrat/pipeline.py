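"""Run configuration, seed registry, file io and the end-to-end pipeline.

``reproduce`` chains every stage on synthetic data: stimulus generation ->
decoder fitting with noise calibration -> informed pair selection -> observer
simulation -> statistics, writing CSV/JSON artefacts plus a hashed manifest.
Identical configuration and seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, decoder, selection, stats, stimuli
from .backbone import SyntheticBackbone

__all__ = ["RunConfig", "stage_seed", "reproduce", "save_png", "write_manifest"]

_STAGES = ("stimuli", "decoder", "selection", "behavior", "analysis")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic named seed per stochastic stage, below 2**31."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """All tunable parameters of one pipeline run.

    The defaults are the full-scale study conditions (100 calibration
    iterations, 10,000 selection iterations, 1,000 permutations, 100
    reliability splits); ``RunConfig.smoke()`` gives a reduced configuration
    for quick end-to-end runs.
    """

    seed: int = 0
    noise_target: float = 0.75
    noise_iters: int = 100
    selection_iters: int = 10_000
    tau_zero: float = 0.5
    tau_high: float = 1.5
    k: int = 7
    n_perm: int = 1000
    n_splits: int = 100
    n_rats: int = 11
    n_humans: int = 45
    sessions_per_protocol: int = 4
    write_images: bool = True
    pool_rotations: tuple = stimuli.ROTATION_ANGLES
    pool_lights: tuple = stimuli.LIGHT_LOCATIONS

    @classmethod
    def smoke(cls, seed: int = 0) -> "RunConfig":
        return cls(seed=seed, noise_iters=25, selection_iters=400,
                   n_perm=200, n_splits=25, n_rats=4, n_humans=6,
                   sessions_per_protocol=2, write_images=False,
                   pool_rotations=(0, 60, 120, 180), pool_lights=("front", "left"))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["pool_rotations"] = list(self.pool_rotations)
        d["pool_lights"] = list(self.pool_lights)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["pool_rotations"] = tuple(d["pool_rotations"])
        d["pool_lights"] = tuple(d["pool_lights"])
        return cls(**d)

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValueError("analysis stage requires n_perm >= 1")
        if self.n_splits < 1:
            raise ValueError("analysis stage requires n_splits >= 1")
        if self.noise_iters < 1 or self.selection_iters < 1:
            raise ValueError("iteration counts must be >= 1")


def save_png(img: stimuli.StimulusImage, path: str | Path) -> None:
    """Write a stimulus as 8-bit grayscale PNG."""
    import imageio.v3 as iio
    iio.imwrite(Path(path), (np.clip(img.pixels, 0, 1) * 255).astype(np.uint8))


def write_manifest(outdir: Path, files: list[Path]) -> Path:
    rows = []
    for f in sorted(files):
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        rows.append({"file": str(f.relative_to(outdir)), "sha256": digest})
    path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _spec_row(spec: stimuli.StimulusSpec) -> dict:
    s, t = spec.shape, spec.transform
    return {
        "spec_id": decoder.spec_id(spec),
        "concavity_level": s.concavity_level, "alignment_level": s.alignment_level,
        "rot_x": t.rot_x, "rot_y": t.rot_y, "rot_z": t.rot_z,
        "light_location": t.light_location, "size_scale": t.size_scale,
        "position": t.position, "role": spec.role,
    }


def reproduce(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage on synthetic data and write a report directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    timings: dict[str, float] = {}
    log: list[str] = []

    def _log(msg: str) -> None:
        log.append(msg)

    def _stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                if exc is not None:
                    _log(f"stage {name!r} FAILED: {exc}")
                    (outdir / "run.log").write_text("\n".join(log) + "\n")
                    raise RuntimeError(f"pipeline stage {name!r} failed") from exc
                _log(f"stage {name!r} done in {timings[name]}s")
        return _Timer()

    # ---- stimuli ----------------------------------------------------------
    with _stage("stimuli"):
        subgrid = stimuli.DEFAULT_SUBGRID
        train_specs, labels = stimuli.training_stimuli(subgrid)
        manifest = pd.DataFrame([_spec_row(s) | {"label": int(l)}
                                 for s, l in zip(train_specs, labels)])
        p = outdir / "training_stimuli.csv"
        manifest.to_csv(p, index=False)
        files.append(p)
        if config.write_images:
            img_dir = outdir / "stimuli"
            img_dir.mkdir(exist_ok=True)
            for s in train_specs:
                fp = img_dir / f"{decoder.spec_id(s)}.png"
                save_png(stimuli.render(s), fp)
                files.append(fp)
        train_imgs = np.stack([stimuli.render(s).pixels for s in train_specs])

    # ---- decoder ----------------------------------------------------------
    with _stage("decoder"):
        seed = stage_seed(config.seed, "decoder")
        bb = SyntheticBackbone()
        noise = decoder.calibrate_noise(bb, train_imgs, labels,
                                        target=config.noise_target,
                                        iters=config.noise_iters, seed=seed)
        ensemble = decoder.fit_readouts(bb, train_imgs, labels, noise=noise, seed=seed)
        p = outdir / "ensemble.npz"
        ensemble.save(p)
        files.append(p)
        _log(f"calibrated noise sd={noise.sd:.4f}, "
             f"achieved accuracy {noise.achieved_accuracy:.3f}")

    # ---- selection --------------------------------------------------------
    with _stage("selection"):
        seed = stage_seed(config.seed, "selection")
        targets, distractors = selection.default_pool(
            subgrid, rotations=config.pool_rotations, lights=config.pool_lights)
        cands = selection.sample_candidates(ensemble, targets, distractors,
                                            n_iter=config.selection_iters, seed=seed)
        cands, early_sd, late_sd = selection.standardize(cands)
        protocols: dict[str, stimuli.ProtocolDef] = {}
        reports = []
        for profile in ("zero_vs_high", "high_vs_zero"):
            crit = selection.SelectionCriteria(profile=profile,
                                               tau_zero=config.tau_zero,
                                               tau_high=config.tau_high, k=config.k)
            res = selection.filter_select(cands, crit)
            protocols[profile] = selection.build_informed_protocol(res, subgrid)
            reports.append(res.report())
            _log(f"{profile}: {res.n_survivors} survivors, "
                 f"{len(res.selected)} picked (underfull={res.underfull})")
        p = outdir / "selection_report.csv"
        pd.concat(reports, ignore_index=True).to_csv(p, index=False)
        files.append(p)

    # ---- behaviour --------------------------------------------------------
    with _stage("behavior"):
        seed = stage_seed(config.seed, "behavior")
        score_frames = []
        for name in stimuli.TEST_PROTOCOLS:
            proto = (protocols[name] if name in protocols
                     else stimuli.protocol_pairs(name, subgrid))
            score_frames.append(decoder.score_pairs(ensemble, proto,
                                                    include_old_pair=True))
        for name in stimuli.TRAINING_PROTOCOLS:
            proto = stimuli.protocol_pairs(name, subgrid)
            score_frames.append(decoder.score_pairs(ensemble, proto))
        scores = pd.concat(score_frames, ignore_index=True)
        p = outdir / "scores.csv"
        scores.to_csv(p, index=False)
        files.append(p)

        rat, human = behavior.species_presets()
        old_id = decoder.pair_id(subgrid.base_target, subgrid.base_distractor)
        proto_offset = {name: j for j, name in enumerate(
            stimuli.TRAINING_PROTOCOLS + stimuli.TEST_PROTOCOLS)}
        trial_frames = []
        for species, observer, n_subj in (("rat", rat, config.n_rats),
                                          ("human", human, config.n_humans)):
            for i in range(n_subj):
                subj = f"{species}-{i:02d}"
                for name in stimuli.TRAINING_PROTOCOLS:
                    sc = scores[(scores["protocol"] == name)]
                    trial_frames.append(behavior.simulate_sessions(
                        observer, sc, behavior.TRAINING_SESSION,
                        n_sessions=config.sessions_per_protocol, subject=subj,
                        seed=seed + 1000 * i + proto_offset[name]))
                for name in stimuli.TEST_PROTOCOLS:
                    sc = scores[(scores["protocol"] == name)]
                    trial_frames.append(behavior.simulate_sessions(
                        observer, sc, behavior.TEST_SESSION,
                        n_sessions=config.sessions_per_protocol, subject=subj,
                        seed=seed + 1000 * i + proto_offset[name],
                        old_pair_id=old_id))
        trials = pd.concat(trial_frames, ignore_index=True)
        p = outdir / "trials.csv"
        trials.to_csv(p, index=False)
        files.append(p)

    # ---- analysis ---------------------------------------------------------
    with _stage("analysis"):
        seed = stage_seed(config.seed, "analysis")
        report: dict = {"config": {"seed": config.seed, "n_perm": config.n_perm,
                                   "n_splits": config.n_splits},
                        "noise": {"sd": ensemble.noise.sd,
                                  "achieved_accuracy": ensemble.noise.achieved_accuracy}}
        test_scores = scores[scores["protocol"].isin(stimuli.TEST_PROTOCOLS)
                             & ~scores["is_old"].fillna(False)]
        pair_order = list(dict.fromkeys(test_scores["pair_id"]))
        score_mat = (test_scores.pivot_table(index="pair_id", columns="sublayer",
                                             values="classification_score")
                     .reindex(pair_order).to_numpy())
        report["n_test_pairs"] = len(pair_order)

        acc_tables = {}
        for species in ("rat", "human"):
            sub = trials[trials["species"].isin([f"{species}_like"])]
            acc = stats.pooled_pair_accuracy(sub, pair_order)
            prof = stats.layer_correlation_profile(acc, score_mat,
                                                   n_perm=config.n_perm, seed=seed)
            reg = stats.layer_regression(acc, score_mat)
            split_r = stats.split_half_reliability(
                sub[sub["protocol"].isin(stimuli.TEST_PROTOCOLS)],
                n_splits=config.n_splits, seed=seed)
            full_r = stats.spearman_brown(split_r)
            acc_tables[species] = acc
            report[species] = {
                "layer_r": prof.r.tolist(),
                "layer_p": prof.p.tolist(),
                "peak_layer": int(np.argmax(prof.r) + 1),
                "regression": {"r_squared": reg.r_squared,
                               "f": reg.f_statistic, "p": reg.f_pvalue,
                               "correlation_scale": reg.correlation_scale},
                "split_half_r": split_r,
                "full_set_r": full_r,
            }
            for name in ("zero_vs_high", "high_vs_zero"):
                pm = stats.accuracy_table(sub, name)
                k = int(pm.table["n_correct"].sum())
                n = int(pm.table["n_trials"].sum())
                pval, ci = stats.binomial_chance_test(k, n)
                report[species][name] = {"accuracy": k / n if n else None,
                                         "n_trials": n, "binomial_p": pval,
                                         "ci": ci}
        keep = np.isfinite(acc_tables["rat"]) & np.isfinite(acc_tables["human"])
        report["species_r"] = float(np.corrcoef(acc_tables["rat"][keep],
                                                acc_tables["human"][keep])[0, 1])
        report["combined_reliability"] = stats.combined_reliability(
            report["rat"]["full_set_r"], report["human"]["full_set_r"])

        comp = stats.species_comparison(
            trials[trials["species"] == "rat_like"],
            trials[trials["species"] == "human_like"])
        report["species_comparison"] = {
            "normalized_t": comp.normalized_t, "normalized_p": comp.normalized_p,
            "interaction_t": comp.interaction_t, "interaction_p": comp.interaction_p,
            "paired_t": {k: list(v) for k, v in comp.paired_t.items()},
        }

        pairs_by_id = {}
        for name in stimuli.TEST_PROTOCOLS:
            proto = (protocols[name] if name in protocols
                     else stimuli.protocol_pairs(name, subgrid))
            for t, d in proto.pairs:
                pairs_by_id.setdefault(decoder.pair_id(t, d), (t, d))
        test_pairs = [pairs_by_id[p] for p in pair_order]
        bvals, br = stats.brightness_predictor(
            (subgrid.base_target, subgrid.base_distractor), test_pairs,
            acc_tables["rat"])
        pvals, pr = stats.pixel_similarity_predictor(
            (subgrid.base_target, subgrid.base_distractor), test_pairs,
            acc_tables["rat"])
        report["brightness_r_rat"] = br
        report["pixel_similarity_r_rat"] = pr

        p = outdir / "report.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True))
        files.append(p)

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    files.append(outdir / "run.log")
    (outdir / "timings.json").write_text(json.dumps(timings, indent=2))
    files.append(outdir / "timings.json")
    config.to_yaml(outdir / "config.yaml")
    files.append(outdir / "config.yaml")
    write_manifest(outdir, files)
    return outdir
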