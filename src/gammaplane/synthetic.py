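"""Synthetic accelerometry cohorts with known Gamma-plane ground truth.

Each persona emits max-deviation magnitude streams with the statistical
structure the signature method assumes: per-entry Gamma parameters that
drift as a reflected random walk on (log a, log b), occasional regime
jumps that produce large shifts (speed spikes) on the Gamma plane, and
occasional bimodal contamination that the dip-test screen should catch.
Presets are anchored to the fitted endpoints observed in the reference
cohort: normal-control-like personas sit at high shape / low scale
(predictive, reliable statistics), late-stage-Parkinson's-like personas
near the Exponential range at low shape / high scale (random, noisy).

Everything is reproducible: one global seed, per-persona sub-seeds spawned
deterministically from it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .accel_io import AccelReading, Session, write_session

__all__ = [
    "Persona",
    "GroundTruthLedger",
    "simulate_persona_stream",
    "simulate_cohort",
    "nc_like_persona",
    "pd_like_persona",
    "default_cohort",
]


@dataclass(frozen=True)
class Persona:
    """Generative parameters for one synthetic participant.

    a0, b0          baseline Gamma shape and scale of the magnitudes
    drift_sd        sd of the per-entry random-walk step on (log a, log b)
    jump_prob       per-entry probability of a regime jump
    jump_scale      jumps multiply (a, b) by factors log-uniform in
                    [1/jump_scale, jump_scale]
    contamination_prob  per-entry probability of bimodal contamination
    """

    persona_id: str
    a0: float
    b0: float
    drift_sd: float = 0.05
    jump_prob: float = 0.05
    jump_scale: float = 4.0
    contamination_prob: float = 0.05
    days: int = 2
    sessions_per_day: int = 4
    readings_per_session: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.a0 > 0 and self.b0 > 0 and self.jump_scale > 0):
            raise ValueError("a0, b0, jump_scale must be positive")
        for p in (self.jump_prob, self.contamination_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")
        if self.readings_per_session < 100:
            raise ValueError("readings_per_session must be >= 100")
        if self.days < 1 or self.sessions_per_day < 1:
            raise ValueError("days and sessions_per_day must be >= 1")


@dataclass
class GroundTruthLedger:
    """Per-entry truths for recovery tests: one record per generated entry."""

    persona_id: str
    seed: int
    true_a: list[float] = field(default_factory=list)
    true_b: list[float] = field(default_factory=list)
    jump_indices: list[int] = field(default_factory=list)
    contamination_indices: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=0)


def _reflect(value: float, lo: float, hi: float) -> float:
    """Reflect a scalar into [lo, hi] (single bounce is enough for small steps)."""
    if value < lo:
        value = 2 * lo - value
    if value > hi:
        value = 2 * hi - value
    return float(np.clip(value, lo, hi))


def simulate_persona_stream(
    persona: Persona, entry_size: int = 100
) -> tuple[list[Session], GroundTruthLedger]:
    """Generate sessions of magnitude readings for one persona.

    Per entry-sized block: random-walk (log a, log b) with reflection at
    [a0/10, 10 a0] x [b0/10, 10 b0]; with probability jump_prob multiply
    (a, b) by independent log-uniform factors in [1/jump_scale,
    jump_scale] (then re-reflect); draw the block i.i.d. Gamma(a, b).
    With probability contamination_prob the block gets a far second mode:
    20% of its samples are replaced by draws near 10x the block's 99th
    percentile.  Readings are stored as 3-vectors whose Euclidean norm
    reproduces the scalar magnitude, so the streams round-trip through the
    session-file dialect.
    """
    rng = np.random.default_rng(persona.seed)
    ledger = GroundTruthLedger(persona_id=persona.persona_id, seed=persona.seed)
    log_a, log_b = np.log(persona.a0), np.log(persona.b0)
    bounds_a = (np.log(persona.a0 / 10), np.log(persona.a0 * 10))
    bounds_b = (np.log(persona.b0 / 10), np.log(persona.b0 * 10))
    log_js = np.log(persona.jump_scale)

    sessions: list[Session] = []
    entry_counter = 0
    for day in range(1, persona.days + 1):
        for ses in range(1, persona.sessions_per_day + 1):
            magnitudes = np.empty(persona.readings_per_session)
            pos = 0
            while pos < persona.readings_per_session:
                block = min(entry_size, persona.readings_per_session - pos)
                if persona.drift_sd > 0:
                    log_a = _reflect(
                        log_a + rng.normal(0, persona.drift_sd), *bounds_a
                    )
                    log_b = _reflect(
                        log_b + rng.normal(0, persona.drift_sd), *bounds_b
                    )
                if rng.random() < persona.jump_prob:
                    log_a = _reflect(log_a + rng.uniform(-log_js, log_js), *bounds_a)
                    log_b = _reflect(log_b + rng.uniform(-log_js, log_js), *bounds_b)
                    ledger.jump_indices.append(entry_counter)
                a, b = np.exp(log_a), np.exp(log_b)
                samples = rng.gamma(a, b, size=block)
                if rng.random() < persona.contamination_prob:
                    far = 10.0 * np.quantile(samples, 0.99)
                    n_contam = max(1, int(round(0.2 * block)))
                    idx = rng.choice(block, size=n_contam, replace=False)
                    samples[idx] = far * (1.0 + 0.01 * rng.standard_normal(n_contam))
                    ledger.contamination_indices.append(entry_counter)
                magnitudes[pos : pos + block] = samples
                ledger.true_a.append(float(a))
                ledger.true_b.append(float(b))
                entry_counter += 1
                pos += block
            # Random direction on the unit sphere carries each magnitude
            # back to a 3-vector so session files look like device output.
            dirs = rng.standard_normal((persona.readings_per_session, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            vecs = np.abs(magnitudes)[:, None] * dirs
            readings = [
                AccelReading(t=float(i), maxdev=tuple(map(float, vecs[i])))
                for i in range(persona.readings_per_session)
            ]
            sessions.append(
                Session(
                    participant_id=persona.persona_id,
                    day_index=day,
                    session_index=ses,
                    readings=readings,
                )
            )
    return sessions, ledger


def nc_like_persona(persona_id: str, seed: int, **overrides) -> Persona:
    """Normal-control-like preset: high shape, low scale, small rare jumps."""
    defaults = dict(
        a0=3.5, b0=0.64, drift_sd=0.05, jump_prob=0.04, jump_scale=3.0,
        contamination_prob=0.03,
    )
    defaults.update(overrides)
    return Persona(persona_id=persona_id, seed=seed, **defaults)


def pd_like_persona(persona_id: str, seed: int, **overrides) -> Persona:
    """Late-stage-PD-like preset: low shape, high scale, larger frequent jumps."""
    defaults = dict(
        a0=0.75, b0=13.4, drift_sd=0.08, jump_prob=0.10, jump_scale=8.0,
        contamination_prob=0.05,
    )
    defaults.update(overrides)
    return Persona(persona_id=persona_id, seed=seed, **defaults)


def default_cohort(seed: int, n_nc: int = 6, n_pd: int = 9, **overrides) -> list[Persona]:
    """NC-like and PD-like personas with sub-seeds spawned from one seed."""
    ss = np.random.SeedSequence(seed)
    subs = ss.spawn(n_nc + n_pd)
    personas = [
        nc_like_persona(f"nc{i+1:02d}", int(subs[i].generate_state(1)[0] % 2**31), **overrides)
        for i in range(n_nc)
    ]
    personas += [
        pd_like_persona(
            f"pd{i+1:02d}", int(subs[n_nc + i].generate_state(1)[0] % 2**31), **overrides
        )
        for i in range(n_pd)
    ]
    return personas


def simulate_cohort(
    personas: list[Persona], out_dir: str | Path, entry_size: int = 100
) -> dict:
    """Write session files and ground-truth JSON for a persona list.

    Layout: out_dir/<persona>/<day>/<session>.csv plus
    out_dir/<persona>/ground_truth.json; returns a manifest with file
    paths and checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"participants": {}}
    for persona in personas:
        sessions, ledger = simulate_persona_stream(persona, entry_size=entry_size)
        pdir = out / persona.persona_id
        files = []
        for s in sessions:
            path = write_session(s, pdir / str(s.day_index) / f"{s.session_index}.csv")
            files.append(
                {
                    "path": str(path.relative_to(out)),
                    "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
                }
            )
        gt = pdir / "ground_truth.json"
        gt.write_text(ledger.to_json())
        manifest["participants"][persona.persona_id] = {
            "files": files,
            "ground_truth": str(gt.relative_to(out)),
            "persona": asdict(persona),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
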