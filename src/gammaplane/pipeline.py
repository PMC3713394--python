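"""End-to-end orchestration: simulate/read -> signatures -> trajectory -> cohort.

The pipeline mirrors the method's eight steps: gather max-deviation
magnitudes per person, chunk into entries, dip-screen and Gamma-fit each
entry, string the (a, b) points into a stochastic trajectory, take the
speed profile and its peaks above 1, Gamma-fit the peaks into a per-person
signature, then cluster and regress at the cohort level and validate
against veridical labels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accel_io import read_participant_dir
from .cohort import CohortScatter, cohort_report
from .datasets import reference_cohort_scatter
from .signatures import (
    DEFAULT_DIP_ALPHA,
    DEFAULT_WINDOW,
    MIN_ENTRIES_PER_PARTICIPANT,
    chunk_entries,
    entry_signatures,
)
from .synthetic import default_cohort, simulate_cohort
from .trajectory import (
    DEFAULT_PEAK_THRESHOLD,
    DEFAULT_SPEED_CUTOFF,
    InsufficientPeaksError,
    InsufficientTrajectoryError,
    build_trajectory,
    extract_peaks,
    person_signature,
    shift_magnitudes,
)

__all__ = ["PipelineConfig", "run_pipeline", "table1_replication"]

log = logging.getLogger("gammaplane")


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline; defaults are the method's published ones."""

    input_dir: str | None = None  # session files; None -> simulate
    output_dir: str = "gammaplane_run"
    simulate: bool = False
    n_nc: int = 6
    n_pd: int = 9
    window: int = DEFAULT_WINDOW
    dip_alpha: float = DEFAULT_DIP_ALPHA
    n_boot: int = 500
    speed_cutoff: float = DEFAULT_SPEED_CUTOFF
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD
    min_entries: int = MIN_ENTRIES_PER_PARTICIPANT
    min_peaks: int = 10
    k: int = 2
    restarts: int = 50
    seed: int = 0
    days: int = 2
    sessions_per_day: int = 4
    readings_per_session: int = 500

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        for name in ("dip_alpha", "speed_cutoff", "peak_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.input_dir is None and not self.simulate:
            raise ValueError("either input_dir or simulate must be given")


def _participant_signature(
    pid: str, series, labels: dict, config: PipelineConfig
) -> dict | None:
    """Run steps 2-6 for one participant; None if the person is excluded."""
    entries = chunk_entries(series, window=config.window)
    estimates, discarded = entry_signatures(
        entries, dip_alpha=config.dip_alpha, n_boot=config.n_boot, seed=config.seed
    )
    log.info("%s: %d entries, %d discarded by dip test", pid, len(entries), discarded)
    if len(estimates) < max(2, config.min_entries):
        log.warning("%s excluded: %d surviving entries", pid, len(estimates))
        return None
    try:
        traj = build_trajectory(estimates, participant_id=pid)
        profile = shift_magnitudes(traj, cutoff=config.speed_cutoff)
        peaks = extract_peaks(profile, threshold=config.peak_threshold)
        sig = person_signature(
            pid,
            peaks,
            profile,
            n_entries=len(estimates),
            n_discarded=discarded,
            min_peaks=config.min_peaks,
        )
    except (InsufficientTrajectoryError, InsufficientPeaksError) as exc:
        log.warning("%s excluded: %s", pid, exc)
        return None
    return {
        "participant": pid,
        "label": labels.get(pid, "PD" if pid.startswith("pd") else "NC"),
        "shape": sig.peak_fit.a,
        "scale": sig.peak_fit.b,
        "ci_a_low": sig.peak_fit.ci_a[0],
        "ci_a_high": sig.peak_fit.ci_a[1],
        "ci_b_low": sig.peak_fit.ci_b[0],
        "ci_b_high": sig.peak_fit.ci_b[1],
        "fano": sig.fano,
        "max_shift": sig.max_shift,
        "median_shift": sig.median_shift,
        "n_peaks": sig.n_peaks,
        "n_entries": sig.n_entries,
        "n_discarded": sig.n_discarded,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole pipeline; returns a manifest of produced artifacts.

    With ``config.simulate`` a synthetic cohort is generated first (ages
    for synthetic personas are drawn once per run for the age regression
    to have a covariate; they carry no generative meaning).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "version": __version__}

    if config.simulate:
        personas = default_cohort(
            config.seed,
            n_nc=config.n_nc,
            n_pd=config.n_pd,
            days=config.days,
            sessions_per_day=config.sessions_per_day,
            readings_per_session=config.readings_per_session,
        )
        data_dir = out / "sessions"
        simulate_cohort(personas, data_dir, entry_size=config.window)
        labels = {
            p.persona_id: ("NC" if p.persona_id.startswith("nc") else "PD")
            for p in personas
        }
        manifest["simulated"] = sorted(labels)
    else:
        data_dir = Path(config.input_dir)  # type: ignore[arg-type]
        meta = data_dir / "cohort_metadata.csv"
        labels = {}
        if meta.is_file():
            mdf = pd.read_csv(meta)
            labels = dict(zip(mdf["participant"], mdf["label"]))

    rows = []
    participant_ids = sorted(
        p.name for p in data_dir.iterdir() if p.is_dir()
    )
    for pid in participant_ids:
        series, warn = read_participant_dir(data_dir, pid)
        if warn.dropped_rows:
            log.warning("%s: dropped %d corrupt rows", pid, warn.dropped_rows)
        row = _participant_signature(pid, series, labels, config)
        if row is not None:
            rows.append(row)

    sig_df = pd.DataFrame(rows)
    sig_path = out / "person_signatures.csv"
    sig_df.to_csv(sig_path, index=False, float_format="%.10g")
    manifest["person_signatures"] = str(sig_path)

    if len(sig_df) >= config.k and sig_df["label"].nunique() >= 1:
        rng = np.random.default_rng(config.seed)
        ages = np.round(rng.uniform(45, 80, size=len(sig_df)))
        scatter = CohortScatter(
            participant_ids=sig_df["participant"].tolist(),
            points=sig_df[["shape", "scale"]].to_numpy(),
            labels=sig_df["label"].tolist(),
            ages=ages,
            max_shifts=sig_df["max_shift"].to_numpy(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cohort_report(
                scatter,
                k=config.k,
                restarts=config.restarts,
                seed=config.seed,
                out_dir=out,
            )
        manifest["cohort_report"] = str(out / "cohort_report.json")
        manifest["n_in_cohort"] = report["n"]
    else:
        log.warning("cohort stage skipped: too few usable participants")
        manifest["cohort_report"] = None

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def table1_replication(
    restarts: int = 50, seed: int = 0, out_dir: str | Path | None = None, drop: str | None = None
) -> dict:
    """Cohort stage on the packaged reference cohort.

    Reproduces the published cohort statistics (power fits, Fano medians,
    clustering misclassification, Fano-vs-distance and age-on-shape
    regressions) from the transcribed per-person signatures alone.
    ``drop`` removes one participant by name to probe robustness.
    """
    scatter = reference_cohort_scatter()
    if drop is not None:
        keep = [i for i, p in enumerate(scatter.participant_ids) if p != drop]
        if len(keep) == len(scatter.participant_ids):
            raise ValueError(f"no such participant {drop!r}")
        scatter = CohortScatter(
            participant_ids=[scatter.participant_ids[i] for i in keep],
            points=scatter.points[keep],
            labels=[scatter.labels[i] for i in keep],
            ages=scatter.ages[keep],
            max_shifts=scatter.max_shifts[keep],
        )
    return cohort_report(scatter, k=2, restarts=restarts, seed=seed, out_dir=out_dir)
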