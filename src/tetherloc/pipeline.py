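"""End-to-end orchestration: simulate (or load) inputs, map cross-links,
discriminate conformer states, localize the tethered domain by ensemble
violation scoring, fit the core into a density map, and write a combined,
fully deterministic report tree.

Every random stage draws its seed from the single top-level ``seed`` so a
re-run of the same config produces byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, confstate, densfit, ensemble, synthetic_data, xlink
from .structio import write_structure

__all__ = ["RunConfig", "run_pipeline", "make_figures", "localization_experiment"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Single config for the full synthetic-data pipeline run.

    All thresholds carry the analysis defaults: 30 Å cross-link cutoff,
    10° fit sampling, FSC 0.5 criterion.
    """

    seed: int | None = None
    out_dir: str = "tetherloc_run"
    # toy complex
    n_core_residues: int = 150
    n_mobile_residues: int = 50
    linker_length: int = 8
    # conformer triple (degrees away from the planted 'closed' geometry)
    n_atpase_residues: int = 120
    angle_open: float = 60.0
    angle_semi_closed: float = 30.0
    # cross-link simulation
    n_true: int = 20
    max_true_distance: float = 30.0
    fp_fraction: float = 0.1
    datasets: tuple[str, ...] = ("analogA", "analogB")
    p_detect: float = 0.72
    # scoring
    cutoff: float = 30.0
    # ensemble
    ensemble_n: int = 5000
    mode: str = "compact"
    k: int = 12
    # density
    resolution: float = 22.0
    voxel: float = 3.0
    angular_step: float = 20.0
    fsc_threshold: float = 0.5
    n_particles: int = 12
    particle_snr: float = 0.5
    handedness_step: float = 45.0

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("config field 'seed' is required: every random "
                              "stage must be explicitly seeded")
        for name in ("n_true", "ensemble_n", "k", "n_particles"):
            if getattr(self, name) < 1:
                raise ConfigError(f"config field {name!r} must be ≥ 1")
        if len(self.datasets) < 1:
            raise ConfigError("config field 'datasets' must name ≥ 1 dataset")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "datasets" in data:
            data["datasets"] = tuple(data["datasets"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["datasets"] = list(d["datasets"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (frozenset, set)):
        return sorted(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def localization_experiment(
    core,
    mobile,
    truth,
    datasets: tuple[str, ...],
    seed: int,
    n_true: int = 20,
    max_true_distance: float = 30.0,
    fp_fraction: float = 0.1,
    p_detect: float = 1.0,
    cutoff: float = 30.0,
    ensemble_n: int = 5000,
    k: int = 12,
    mode: str = "compact",
) -> dict:
    """Tethered-domain localization: simulate inter-body cross-links on the
    true assembly, score a placement ensemble per dataset, select top-k and
    measure cross-dataset convergence and recovery of the true placement."""
    asm = synthetic_data.assemble(core, mobile, truth)
    core_chain = list(core.chains)[0]
    mobile_chain = list(mobile.chains)[0]
    tspec = ensemble.TetherSpec(
        core_anchor=(core_chain, core.chains[core_chain][-1].seq_id),
        mobile_anchor=(mobile_chain, mobile.chains[mobile_chain][0].seq_id),
        mode=mode,
    )
    members = ensemble.generate_ensemble(core, mobile, tspec, n=ensemble_n,
                                         seed=seed)
    xs = synthetic_data.XlinkSimSpec(
        n_true=n_true, max_true_distance=max_true_distance,
        fp_fraction=fp_fraction, datasets=datasets, seed=seed + 1,
        interchain_only=True, p_detect=p_detect,
    )
    links = synthetic_data.simulate_crosslinks(asm, xs)
    bc = mobile.ca_array().mean(axis=0)
    truth_c = truth.apply(bc)
    per_dataset = {}
    tops = []
    for ds in datasets:
        sub = links.subset(lambda r, d=ds: r.dataset == d)
        info = ensemble.score_ensemble(members, core, mobile, sub, cutoff=cutoff)
        top = ensemble.select_best(members, k)
        tops.append(top)
        per_dataset[ds] = {
            "n_restraints": info["n_restraints"],
            "min_violations": top[0].violations,
            "top_indices": [m.index for m in top],
            "centroid_error": float(
                np.linalg.norm(top[0].placement.apply(bc) - truth_c)
            ),
        }
    conv = ensemble.convergence(tops[0], tops[-1]) if len(tops) > 1 else None
    spread_top = ensemble.placement_spread(tops[0], mobile)
    ref = members[:: max(1, len(members) // 40)][:40]
    spread_all = ensemble.placement_spread(ref, mobile)
    return {
        "members": members,
        "crosslinks": links,
        "tops": tops,
        "per_dataset": per_dataset,
        "convergence": conv,
        "top_mean_pairwise_rmsd": spread_top["mean_pairwise_rmsd"],
        "ensemble_mean_pairwise_rmsd": spread_all["mean_pairwise_rmsd"],
        "orientation_spread_deg": spread_top["orientation_spread_deg"],
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in dependency order and write the report tree.

    Any stage error aborts with the stage name while keeping the artifacts
    written so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "package_version": __version__,
        }
    }
    seed = int(config.seed)

    stage = "simulate_complex"
    try:
        spec = synthetic_data.ToyComplexSpec(
            n_core_residues=config.n_core_residues,
            n_mobile_residues=config.n_mobile_residues,
            linker_length=config.linker_length,
            seed=seed,
        )
        core, mobile, truth = synthetic_data.make_toy_complex(spec)
        asm = synthetic_data.assemble(core, mobile, truth)
        write_structure(core, out / "core.pdb")
        write_structure(mobile, out / "mobile.pdb")
        write_structure(asm, out / "assembled.pdb")

        stage = "confstate"
        # the state discrimination concerns a two-lobe ATPase-like domain
        # whose inter-lobe distances bracket the cutoff; the tethered toy
        # mobile is too small for that, so this stage gets its own stand-in
        n_lobe = config.n_atpase_residues // 2
        atpase = hinge = conformers = None
        for attempt in range(16):  # some lobe draws admit no clash-free hinge
            try:
                atpase, hinge = synthetic_data.make_two_lobe_domain(
                    n_lobe, config.n_atpase_residues - n_lobe,
                    seed + 5 + 97 * attempt,
                )
                conformers = synthetic_data.make_conformer_triple(
                    atpase, hinge,
                    angles=(config.angle_open, config.angle_semi_closed, 0.0),
                    labels=("open", "semi-closed", "closed"),
                )
                break
            except synthetic_data.GenerationError:
                continue
        if conformers is None:
            raise synthetic_data.GenerationError(
                "no clash-free two-lobe conformer triple in 16 attempts"
            )
        ixs = synthetic_data.XlinkSimSpec(
            n_true=config.n_true, max_true_distance=config.max_true_distance,
            fp_fraction=0.0, datasets=config.datasets, seed=seed + 11,
            p_detect=config.p_detect,
        )
        intralinks = _interlobe_links(atpase, hinge, ixs)
        table = _conformer_table(intralinks, conformers, config.datasets)
        classes = confstate.classify_linkages(table, cutoff=config.cutoff)
        verdicts = confstate.infer_state(classes, list(config.datasets),
                                         set(table.models))
        confstate.state_report(classes, verdicts, out)
        report["confstate"] = {
            "summary": confstate.detection_summary(classes),
            "verdicts": verdicts,
        }

        stage = "localization"
        loc = localization_experiment(
            core, mobile, truth, config.datasets, seed=seed + 23,
            n_true=config.n_true, max_true_distance=config.max_true_distance,
            fp_fraction=config.fp_fraction, p_detect=config.p_detect,
            cutoff=config.cutoff, ensemble_n=config.ensemble_n, k=config.k,
            mode=config.mode,
        )
        xlink.write_crosslinks(loc["crosslinks"], out / "crosslinks.tsv")
        _write_scores(loc["members"], out / "ensemble_scores.tsv")
        report["localization"] = {
            "per_dataset": loc["per_dataset"],
            "convergence": loc["convergence"],
            "top_mean_pairwise_rmsd": loc["top_mean_pairwise_rmsd"],
            "ensemble_mean_pairwise_rmsd": loc["ensemble_mean_pairwise_rmsd"],
            "orientation_spread_deg": loc["orientation_spread_deg"],
        }

        stage = "density_fit"
        dmap = synthetic_data.simulate_density(
            asm, resolution=config.resolution, voxel=config.voxel, pad=12.0
        )
        dmap.write_ccp4(out / "map.ccp4")
        fits = densfit.exhaustive_fit(
            dmap, core, angular_step=config.angular_step,
            lowpass_to=config.resolution, laplacian_filter=True, n_results=5,
        )
        fits_m = densfit.exhaustive_fit(
            densfit.mirror(dmap), core, angular_step=config.angular_step,
            lowpass_to=config.resolution, laplacian_filter=True, n_results=1,
        )
        target_vol = densfit.model_volume(asm)
        thr = densfit.contour_by_volume(dmap, target_vol)
        seg, seg_info = densfit.residual_segment(
            fitted=core, dmap=dmap, threshold=thr, resolution=config.resolution
        )
        seg.write_ccp4(out / "residual_segment.ccp4")
        report["density_fit"] = {
            "best_ccc": fits[0].ccc,
            "mirrored_best_ccc": fits_m[0].ccc,
            "ccc_margin_over_mirror": fits[0].ccc - fits_m[0].ccc,
            "fit_translation": fits[0].transform.translation,
            "contour_threshold": thr,
            "contour_target_volume": target_vol,
            "residual_segment": seg_info,
        }

        stage = "fsc"
        rng = np.random.default_rng(seed + 31)
        noise_sd = float(dmap.grid.std()) * 0.5
        half_a = densfit.DensityMap(
            dmap.grid + rng.normal(scale=noise_sd, size=dmap.shape),
            dmap.voxel, dmap.origin,
        )
        half_b = densfit.DensityMap(
            dmap.grid + rng.normal(scale=noise_sd, size=dmap.shape),
            dmap.voxel, dmap.origin,
        )
        curve = densfit.fsc(half_a, half_b)
        resolution = densfit.resolution_at(curve, config.fsc_threshold)
        pd.DataFrame(
            {"frequency": curve.frequencies, "fsc": curve.values}
        ).to_csv(out / "fsc.tsv", sep="\t", index=False)
        report["fsc"] = {
            "resolution": resolution,
            "threshold": config.fsc_threshold,
        }

        stage = "handedness"
        sol = synthetic_data.make_solenoid()
        smap = synthetic_data.simulate_density(
            sol, resolution=config.resolution, voxel=3.5, pad=12.0
        )
        particles = synthetic_data.simulate_particles(
            smap, n=config.n_particles, snr=config.particle_snr, seed=seed + 41
        )
        hand = densfit.handedness_test(
            particles, smap, angular_step=config.handedness_step
        )
        report["handedness"] = {
            "mean_delta_ccc": hand["mean_delta_ccc"],
            "fraction_positive": hand["fraction_positive"],
            "p_value": hand["p_value"],
            "n_particles": config.n_particles,
        }
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        _dump_json(report, out / "report.json")
        raise StageError(stage, exc) from exc

    _dump_json(report, out / "report.json")
    return report


def _interlobe_links(mobile, hinge, spec):
    """Simulated links restricted to pairs straddling the hinge: the chain is
    temporarily split into its two lobes so the cross-link simulator's
    inter-chain sampling draws only lobe-1/lobe-2 pairs, and the records are
    remapped back onto the single-chain numbering."""
    from .structio import StructureModel
    from .xlink import CrosslinkRecord, CrosslinkSet

    chain = list(mobile.chains)[0]
    residues = mobile.chains[chain]
    split = StructureModel(
        "lobes",
        {
            "1": [dataclasses.replace(r, chain_id="1")
                  for r in mobile.copy().chains[chain] if r.seq_id < hinge],
            "2": [dataclasses.replace(r, chain_id="2")
                  for r in mobile.copy().chains[chain] if r.seq_id >= hinge],
        },
    )
    spec = dataclasses.replace(spec, interchain_only=True)
    picked = synthetic_data.simulate_crosslinks(split, spec)
    records = [
        CrosslinkRecord((chain, r.site_a[1]), (chain, r.site_b[1]),
                        r.dataset, r.count)
        for r in picked.records
    ]
    if not records:
        raise ValueError("no hinge-straddling links simulated")
    return CrosslinkSet(records)


def _conformer_table(links, conformers, datasets):
    rows = {}
    for r in links.records:
        key = (r.site_a[1], r.site_b[1])
        row = rows.setdefault(
            key,
            {"res_a": key[0], "res_b": key[1],
             **{f"n_{d}": 0 for d in datasets}},
        )
        row[f"n_{r.dataset}"] += r.count
    for key, row in rows.items():
        for label, model in conformers.items():
            chain = list(model.chains)[0]
            from .structio import ca_distance

            row[f"d_{label}"] = ca_distance(
                model, (chain, key[0]), (chain, key[1])
            )
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["res_a"], r["res_b"])))
    return confstate.ConformerDistanceTable(df)


def _write_scores(members, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "index": m.index,
                "violations": m.violations,
                "sum_restraint_distance": round(m.sum_restraint_distance, 3)
                if m.sum_restraint_distance is not None else None,
                "mappable_restraints": m.mappable_restraints,
            }
            for m in members
        ]
    ).to_csv(path, sep="\t", index=False)


def make_figures(report: dict, out_dir: str | Path) -> list[Path]:
    """Deterministic summary figures for a finished run; purely cosmetic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    made = []

    fsc_path = out / "fsc.tsv"
    if fsc_path.exists():
        df = pd.read_csv(fsc_path, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(df.frequency, df.fsc)
        thr = report.get("fsc", {}).get("threshold", 0.5)
        ax.axhline(thr, ls="--", c="gray")
        ax.set_xlabel("spatial frequency (1/Å)")
        ax.set_ylabel("FSC")
        fig.tight_layout()
        p = out / "fig_fsc.png"
        fig.savefig(p)
        plt.close(fig)
        made.append(p)

    scores_path = out / "ensemble_scores.tsv"
    if scores_path.exists():
        df = pd.read_csv(scores_path, sep="\t")
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(df.violations, bins=range(int(df.violations.max()) + 2))
        ax.set_xlabel("cross-link violations")
        ax.set_ylabel("ensemble members")
        fig.tight_layout()
        p = out / "fig_violations.png"
        fig.savefig(p)
        plt.close(fig)
        made.append(p)

    xl_path = out / "crosslinks.tsv"
    if xl_path.exists():
        df = pd.read_csv(xl_path, sep="\t")
        if len(df) == 0:
            import warnings

            warnings.warn("empty cross-link set: skipping cross-link figure")
        else:
            fig, ax = plt.subplots(figsize=(4, 3))
            for i, (_, r) in enumerate(df.iterrows()):
                ax.plot([r.res_a, r.res_b], [i, i], "k-", lw=0.8)
            ax.set_xlabel("residue")
            ax.set_ylabel("cross-link")
            fig.tight_layout()
            p = out / "fig_crosslinks.png"
            fig.savefig(p)
            plt.close(fig)
            made.append(p)

    if "handedness" in report:
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.bar([0], [report["handedness"]["mean_delta_ccc"]])
        ax.axhline(0, c="k", lw=0.8)
        ax.set_xticks([0], ["map hand"])
        ax.set_ylabel("mean ΔCCC")
        fig.tight_layout()
        p = out / "fig_handedness.png"
        fig.savefig(p)
        plt.close(fig)
        made.append(p)
    return made
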