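"""End-to-end orchestration: ensemble in, per-Rg-group analyses out.

``run_decomposition`` reads (or generates) an ensemble, partitions it into
Rg groups, runs the enabled analyses per selected group, and writes every
result as flat text together with a manifest recording inputs, parameters,
the seed, and a SHA-256 checksum per output file — identical config + seed
reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .ensemble_io import (Ensemble, ScatteringProfile, read_pdb_ensemble,
                          read_saxs_curve, write_group_index, write_saxs_curve)
from .flexibility import (featurize, free_energy_landscape, gromos_cluster,
                          rmsf_per_group, tica_fit)
from .rg import RgGroupSet, assign_rg_groups, group_histogram
from .scattering import (average_profile, chi_squared, default_q_grid,
                         kratky_transform, pair_distance_distribution)
from .secondary import (DEFAULT_REGIONS, backbone_dihedrals, group_ss_fractions,
                        region_fractions, SS_LABELS)
from .surface import (hbond_map, normalized_sasa, residue_distance_map,
                      residue_sasa, sasa_per_group)
from .synthetic import GeneratorConfig, generate_ensemble
from .rg import radius_of_gyration

log = logging.getLogger("coedecomp")

ALL_ANALYSES = (
    "rg_histogram", "scattering", "pr", "sasa", "hbonds", "contacts",
    "rmsf", "clusters", "tica", "ramachandran", "dssp",
)


@dataclass
class RunConfig:
    """Configuration of one decomposition run.

    Exactly one of ``input_pdb`` / ``generator`` must be set. ``groups``
    selects which Rg groups get the per-group analyses: ``"all"``, a list of
    integer labels, or ``"top-<k>"`` for the k most populated. Unknown keys
    in a config file are rejected.
    """

    output_dir: str = "coedecomp_out"
    input_pdb: Optional[str] = None
    generator: Optional[dict] = None
    analyses: Sequence[str] = ALL_ANALYSES
    groups: object = "top-4"
    seed: int = 0
    q_max: float = 0.5
    n_q: int = 101
    pr_bin_width: float = 1.0
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 30.0
    contact_mode: str = "min-atom"
    cluster_rmsd_cutoff: float = 7.0
    tica_lag: int = 10
    landscape_bins: int = 60
    ramachandran_bin_width: float = 2.0
    low_sampling_fraction: float = 0.001

    def __post_init__(self) -> None:
        if (self.input_pdb is None) == (self.generator is None):
            raise ValueError("set exactly one of input_pdb / generator")
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses {sorted(unknown)}; available: {ALL_ANALYSES}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_profile(profile: ScatteringProfile, path: Path) -> None:
    write_saxs_curve(profile, path)


def _selected_labels(groups: RgGroupSet, selector) -> list[int]:
    if selector == "all":
        return list(groups.labels)
    if isinstance(selector, str) and selector.startswith("top-"):
        return groups.top_k_labels(int(selector[4:]))
    labels = [int(s) for s in selector]
    missing = [l for l in labels if l not in groups.members]
    if missing:
        raise KeyError(f"requested group(s) {missing} absent; available: {groups.labels}")
    return sorted(labels)


def run_decomposition(config: RunConfig) -> dict:
    """Execute the configured decomposition; returns the manifest dict.

    Every produced file lands in ``config.output_dir`` and is listed in the
    manifest (written as ``manifest.json`` there) with its SHA-256 checksum.
    Analyses that need ≥2 frames skip singleton groups with a logged warning.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def emit(name: str) -> Path:
        return out / name

    def register(path: Path) -> None:
        files[path.name] = _sha256(path)

    if config.generator is not None:
        gen = dict(config.generator)
        gen.setdefault("seed", config.seed)
        gcfg = GeneratorConfig(**gen)
        log.info("generating synthetic ensemble: %d frames, seed %d", gcfg.n_frames, gcfg.seed)
        ensemble = generate_ensemble(gcfg)
        source = {"generator": gen}
    else:
        log.info("reading ensemble from %s", config.input_pdb)
        ensemble = read_pdb_ensemble(config.input_pdb)
        source = {"input_pdb": str(config.input_pdb)}

    groups = assign_rg_groups(ensemble, config.low_sampling_fraction)
    selected = _selected_labels(groups, config.groups)
    log.info("%d frames -> %d Rg groups %s; analysing %s",
             ensemble.n_frames, len(groups.labels), groups.labels, selected)
    low = groups.low_sampling_labels()
    if low:
        log.warning("low-sampling groups (under %.2f%% of frames): %s",
                    100 * config.low_sampling_fraction, low)

    ndx = emit("rg_groups.ndx")
    write_group_index(groups, ndx)
    register(ndx)

    analyses = set(config.analyses)
    q_grid = np.linspace(0.0, config.q_max, config.n_q)

    if "rg_histogram" in analyses:
        hist = group_histogram(groups)
        p = emit("rg_histogram.tsv")
        with open(p, "w") as fh:
            fh.write("label\tcount\tfraction\tmean_rg\tlow_sampling\n")
            for lab, (count, frac) in hist.items():
                fh.write(f"{lab}\t{count}\t{frac:.8g}\t{groups.mean_rg(lab):.6g}\t{int(lab in low)}\n")
        register(p)

    if "scattering" in analyses:
        t = time.time()
        global_profile = average_profile(ensemble, None, q_grid)
        p = emit("profile_all.dat")
        _write_profile(global_profile, p)
        register(p)
        k = emit("kratky_all.dat")
        np.savetxt(k, kratky_transform(global_profile), fmt="%.8e")
        register(k)
        for lab in selected:
            prof = average_profile(ensemble, groups.members[lab], q_grid)
            p = emit(f"profile_rg{lab}.dat")
            _write_profile(prof, p)
            register(p)
            k = emit(f"kratky_rg{lab}.dat")
            np.savetxt(k, kratky_transform(prof), fmt="%.8e")
            register(k)
        log.info("scattering averages done in %.1fs", time.time() - t)

    if "pr" in analyses:
        for tag, idx in [("all", None)] + [(f"rg{l}", groups.members[l]) for l in selected]:
            dist = pair_distance_distribution(ensemble, idx, config.pr_bin_width)
            p = emit(f"pr_{tag}.dat")
            with open(p, "w") as fh:
                fh.write(f"# r_max {dist.r_max:.6f}\n")
                np.savetxt(fh, np.column_stack([dist.r, dist.p]), fmt="%.8e")
            register(p)

    if "sasa" in analyses:
        t = time.time()
        observed = sasa_per_group(ensemble, groups, selected,
                                  config.sasa_probe_radius, config.sasa_n_points)
        p = emit("sasa_raw.tsv")
        observed.write_tsv(p)
        register(p)
        norm = normalized_sasa(observed, ensemble.topology.residue_name)
        p = emit("sasa_normalized.tsv")
        norm.write_tsv(p)
        register(p)
        # per-frame totals for the (Rg, SASA) density diagnostic
        totals = np.array([
            residue_sasa(ensemble.coords[fi], ensemble.topology,
                         config.sasa_probe_radius, config.sasa_n_points).sum()
            for fi in range(ensemble.n_frames)
        ])
        p = emit("sasa_total_per_frame.tsv")
        np.savetxt(p, np.column_stack([groups.rg_per_frame, totals]),
                   fmt="%.6f", header="rg\ttotal_sasa")
        register(p)
        log.info("SASA done in %.1fs", time.time() - t)

    if "hbonds" in analyses:
        maps = hbond_map(ensemble, groups, selected,
                         config.hbond_distance_cutoff, config.hbond_angle_cutoff)
        for lab, (occ, records) in maps.items():
            p = emit(f"hbonds_rg{lab}.tsv")
            with open(p, "w") as fh:
                fh.write("residue_i\tresidue_j\toccupancy\n")
                labels = ensemble.topology.residue_labels
                for r in records:
                    fh.write(f"{labels[r.donor_res - 1]}\t{labels[r.acceptor_res - 1]}\t{r.occupancy:.6g}\n")
            register(p)

    if "contacts" in analyses:
        dmaps = residue_distance_map(ensemble, groups, selected, config.contact_mode)
        for lab, mat in dmaps.items():
            p = emit(f"contacts_rg{lab}.tsv")
            np.savetxt(p, mat, fmt="%.4f", delimiter="\t")
            register(p)

    if "rmsf" in analyses:
        usable = [l for l in selected if len(groups.members[l]) >= 2]
        skipped = sorted(set(selected) - set(usable))
        if skipped:
            log.warning("RMSF skipped for singleton group(s) %s", skipped)
        if usable:
            rmsf = rmsf_per_group(ensemble, groups, usable)
            p = emit("rmsf.tsv")
            rmsf.write_tsv(p)
            register(p)

    if "clusters" in analyses:
        for lab in selected:
            clusters = gromos_cluster(ensemble, groups.members[lab],
                                      config.cluster_rmsd_cutoff)
            p = emit(f"clusters_rg{lab}.tsv")
            with open(p, "w") as fh:
                fh.write("frame\tcluster\tis_center\n")
                for ci, cl in enumerate(clusters):
                    for m in cl.members:
                        fh.write(f"{m}\t{ci}\t{int(m == cl.center)}\n")
            register(p)

    if "tica" in analyses:
        feats = featurize(ensemble)
        for lab in selected:
            idx = groups.members[lab]
            if len(idx) <= config.tica_lag + 2:
                log.warning("tICA skipped for group %d (%d frames <= lag %d)",
                            lab, len(idx), config.tica_lag)
                continue
            model = tica_fit(feats[idx], lag=config.tica_lag, n_components=2)
            proj = model.transform(feats[idx])
            try:
                scape = free_energy_landscape(proj, config.landscape_bins)
            except ValueError as exc:
                log.warning("landscape skipped for group %d: %s", lab, exc)
                continue
            p = emit(f"landscape_rg{lab}.tsv")
            scape.write_tsv(p)
            register(p)
            p = emit(f"tica_rg{lab}.txt")
            with open(p, "w") as fh:
                fh.write(f"lag {model.lag}\nregularization {model.regularization:.8g}\n")
                fh.write("eigenvalues " + " ".join(f"{v:.8g}" for v in model.eigenvalues) + "\n")
            register(p)

    if "ramachandran" in analyses:
        dih = backbone_dihedrals(ensemble)
        fr_all = region_fractions(dih)
        p = emit("region_fractions.tsv")
        with open(p, "w") as fh:
            fh.write("group\t" + "\t".join(DEFAULT_REGIONS.names()) + "\n")
            fh.write("all\t" + "\t".join(f"{fr_all[n]:.6g}" for n in DEFAULT_REGIONS.names()) + "\n")
            for lab in selected:
                idx = groups.members[lab]
                sub = region_fractions(
                    type(dih)(dih.phi[idx], dih.psi[idx]))
                fh.write(f"{lab}\t" + "\t".join(f"{sub[n]:.6g}" for n in DEFAULT_REGIONS.names()) + "\n")
        register(p)

    if "dssp" in analyses:
        fractions = group_ss_fractions(ensemble, groups, selected)
        p = emit("ss_fractions.tsv")
        with open(p, "w") as fh:
            fh.write("group\t" + "\t".join(SS_LABELS) + "\n")
            for lab in selected:
                fh.write(f"{lab}\t" + "\t".join(f"{fractions[lab][s]:.6g}" for s in SS_LABELS) + "\n")
        register(p)

    manifest = {
        "package": "coedecomp",
        "version": __version__,
        "seed": config.seed,
        "source": source,
        "n_frames": ensemble.n_frames,
        "n_atoms": ensemble.n_atoms,
        "parameters": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in vars(config).items() if k not in ("generator",)
        },
        "groups": {str(l): int(len(groups.members[l])) for l in groups.labels},
        "selected_groups": [int(l) for l in selected],
        "low_sampling_groups": [int(l) for l in low],
        "files": dict(sorted(files.items())),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run finished in %.1fs; %d files", time.time() - t0, len(files))
    return manifest


def compare_to_experiment(manifest_path, curve_path, fit_scale: bool = True) -> dict[str, tuple[float, float]]:
    """χ² of the run's global and per-group average profiles vs a measured curve.

    Returns {profile tag: (χ², fitted scale)}; raises if the run produced no
    scattering averages or the q ranges do not overlap.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    outdir = manifest_path.parent
    exp = read_saxs_curve(curve_path)
    results: dict[str, tuple[float, float]] = {}
    names = [n for n in manifest["files"] if n.startswith("profile_")]
    if "profile_all.dat" not in names:
        raise ValueError("manifest has no global average profile (run the 'scattering' analysis)")
    for name in sorted(names):
        sim = read_saxs_curve(outdir / name)
        tag = name[len("profile_"):-len(".dat")]
        results[tag] = chi_squared(exp, sim, fit_scale=fit_scale)
    return results
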