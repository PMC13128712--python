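"""End-to-end orchestration: cohorts in, analysis artifacts out.

A run takes cohorts (either loaded from the three CSV schemas or simulated
from archetype presets) and writes, into one run directory:

* surface_stats.csv — tribological statistics per specimen x digit
* overbite_summary.json, tooth_summary.json — cohort summaries
* occlusion.csv — within-individual transport distances (peak/gullet/mean)
* distance_matrix.csv + skip_report.json — cross-digit transport matrix
* omega_<species>_<digit>.csv — Ω SSCP matrices with station labels
* bw_distances.csv — Bures–Wasserstein distances between the Ω matrices
* ordination.csv — MDS coordinates (stress in the header comment)
* network_edges.csv — trophic-character Manhattan network (+ MST flags)
* manifest.json — config hash, seed, package version
* report.md — human-readable run summary

Every table carries a leading ``#`` comment declaring its units, and every
artifact is reproducible from the config and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .occlusion import cross_digit_distance_matrix, occlusive_distance
from .omega import OmegaMatrix, assemble_profile_matrix, bures_wasserstein, omega
from .ordination import CharacterTable, manhattan_network, metric_mds
from .profile_model import Cohort, Digit, OcclumorphError, ValidationError, load_specimens
from .synthetic_data import archetype_presets, generate_cohorts
from .tribology import cohort_surface_stats, overbite_summary, tooth_summary

__all__ = ["RunConfig", "run_pipeline", "synthetic_character_table"]

log = logging.getLogger("occlumorph")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either the three CSV paths, or a simulate
    block (presets is None → the four archetype presets).
    """

    out_dir: str
    profiles: Optional[str] = None
    specimens: Optional[str] = None
    asperities: Optional[str] = None
    simulate: bool = False
    preset_codes: Optional[list] = None
    n_per_species: int = 20
    seed: int = 0
    normalize_locations: bool = True
    run: str = "mean"
    digit_selector: str = "both"
    uniform_fallback: bool = False
    k_range: tuple = (2, 18)
    mds_dim: int = 2
    mds_seed: int = 0
    mds_tol: float = 1e-9
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        paths = (self.profiles, self.specimens, self.asperities)
        have_paths = all(p is not None for p in paths)
        if self.simulate == have_paths:
            raise ValidationError(
                "exactly one of {input paths, simulate} must be configured"
            )
        k0, k1 = self.k_range
        if not (2 <= k0 <= k1 <= 18):
            raise ValidationError("k_range must lie within 2..18")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, units_comment: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {units_comment}\n")
        df.to_csv(fh, index=index)


def synthetic_character_table(cohorts) -> CharacterTable:
    """Coarse integer-coded trophic character table derived from cohorts.

    Synthetic stand-in for the external field-use look-up table: characters
    are ordinal codes of computed cohort summaries (tooth counts, overbite
    class, pocket presence, blade dominance), good enough to exercise the
    network stage end to end.
    """
    rows, labels = [], []
    for cohort in cohorts:
        stats = cohort_surface_stats([cohort])
        ts = tooth_summary(cohort)
        ob = overbite_summary(cohort)
        md_peaks = stats.loc[stats.digit == "md", "n_peaks"].mean()
        fd_peaks = stats.loc[stats.digit == "fd", "n_peaks"].mean()
        rq = stats["Rq_um"].mean()
        ft_share = ts.mean_count[("md", "FT")] / max(
            ts.mean_count[("md", "ATB")] + ts.mean_count[("md", "FT")], 1e-9
        )
        labels.append(cohort.species_code)
        rows.append([
            int(round(md_peaks)),
            int(round(fd_peaks)),
            int(ob.p_overbite > 0.65),
            int(ft_share > 0.6),
            int(round(2 * rq)),
        ])
    return CharacterTable(
        labels=labels,
        characters=["md_teeth", "fd_teeth", "overbite", "blade_md", "roughness_class"],
        values=np.asarray(rows, dtype=float),
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    A stage failure leaves partial outputs in place beside a FAILED marker
    naming the stage, and re-raises.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    t0 = time.time()
    try:
        stage = "input"
        if config.simulate:
            presets = archetype_presets()
            if config.preset_codes:
                presets = {c: presets[c] for c in config.preset_codes}
            cohorts = generate_cohorts(
                presets, n_per_species=config.n_per_species, seed=config.seed, out_dir=out
            )
        else:
            cohorts = load_specimens(config.profiles, config.specimens, config.asperities)
        log.info("loaded %d cohorts (%d specimens)", len(cohorts), sum(len(c) for c in cohorts))

        stage = "surface_stats"
        stats = cohort_surface_stats(cohorts)
        _write_csv(stats, out / "surface_stats.csv",
                   "units: lengths um, sigma2 um^2; one row per specimen x digit")

        stage = "overbite_summary"
        ob = {
            c.species_code: dataclasses.asdict(overbite_summary(c)) for c in cohorts
        }
        (out / "overbite_summary.json").write_text(json.dumps(ob, indent=2, sort_keys=True))

        stage = "tooth_summary"
        tooth = {}
        for c in cohorts:
            ts = tooth_summary(c)
            tooth[c.species_code] = {
                "mean_count": {f"{d}:{t}": v for (d, t), v in ts.mean_count.items()},
                "transition": {d: m.tolist() for d, m in ts.transition.items()},
                "row_support": {d: list(s) for d, s in ts.row_support.items()},
            }
        (out / "tooth_summary.json").write_text(json.dumps(tooth, indent=2, sort_keys=True))

        stage = "occlusion"
        occ_rows = []
        for c in cohorts:
            for s in c.specimens:
                d = occlusive_distance(s, uniform_fallback=config.uniform_fallback)
                occ_rows.append({
                    "specimen_id": s.specimen_id, "species_code": s.species_code,
                    "d_peak": d.d_peak, "d_gullet": d.d_gullet, "d_mean": d.d_mean,
                })
        _write_csv(pd.DataFrame(occ_rows), out / "occlusion.csv",
                   "units: transport work, um (raw within-individual locations)")

        stage = "distance_matrix"
        dm, skips = cross_digit_distance_matrix(
            cohorts, digit_selector=config.digit_selector, run=config.run,
            normalize_locations=config.normalize_locations,
            uniform_fallback=config.uniform_fallback,
        )
        _write_csv(dm.to_frame(), out / "distance_matrix.csv",
                   "units: transport work on x/x_ie-normalized locations"
                   if config.normalize_locations else "units: transport work, um",
                   index=True)
        (out / "skip_report.json").write_text(json.dumps(skips, indent=2))

        stage = "omega"
        omegas: dict[tuple, OmegaMatrix] = {}
        k0, k1 = config.k_range
        station_labels = [f"k{k}" for k in range(k0, k1 + 1)]
        for c in cohorts:
            for digit in (Digit.MOVEABLE, Digit.FIXED):
                Y = assemble_profile_matrix(c, digit, (k0, k1))
                om = omega(Y, (k0, k1), label=(c.species_code, digit.value))
                omegas[(c.species_code, digit.value)] = om
                _write_csv(
                    pd.DataFrame(om.values, index=station_labels, columns=station_labels),
                    out / f"omega_{c.species_code}_{digit.value}.csv",
                    f"units: um^2; avSSCP over n={om.n} specimens, stations {k0}..{k1}",
                    index=True,
                )

        stage = "bw_distances"
        keys = list(omegas)
        bw_rows = []
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                bw_rows.append({
                    "a": f"{a[0]}:{a[1]}", "b": f"{b[0]}:{b[1]}",
                    "bw_distance": bures_wasserstein(omegas[a], omegas[b]),
                })
        _write_csv(pd.DataFrame(bw_rows), out / "bw_distances.csv",
                   "units: um (Bures-Wasserstein on avSSCP matrices)")

        stage = "ordination"
        res = metric_mds(dm, k=config.mds_dim, seed=config.mds_seed, tol=config.mds_tol)
        coords = pd.DataFrame(
            res.coordinates, columns=[f"dim{i + 1}" for i in range(config.mds_dim)]
        )
        coords.insert(0, "label", res.labels)
        coords.insert(1, "species_code", res.groups)
        _write_csv(coords, out / "ordination.csv",
                   f"metric MDS (stress-1 = {res.stress:.6f}, iterations = {res.iterations}, "
                   f"converged = {res.converged}); coordinates unitless")

        stage = "network"
        if len(cohorts) >= 2:
            edges = manhattan_network(synthetic_character_table(cohorts))
        else:
            edges = pd.DataFrame(columns=["a", "b", "weight", "in_mst"])
            log.info("network stage skipped: fewer than two species")
        _write_csv(edges, out / "network_edges.csv",
                   "unweighted Manhattan distances on synthetic trophic character codes")

        stage = "report"
        lines = [
            "# Occlusal analysis run summary", "",
            f"- cohorts: {', '.join(c.species_code for c in cohorts)}",
            f"- specimens: {sum(len(c) for c in cohorts)}",
            f"- MDS stress-1: {res.stress:.4f} ({res.iterations} iterations)",
            f"- skipped digits: {len(skips)}",
            f"- elapsed: {time.time() - t0:.1f} s",
        ]
        (out / "report.md").write_text("\n".join(lines) + "\n")

        manifest = {
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise
    return out
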