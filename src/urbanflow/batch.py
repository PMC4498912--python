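"""Reproducible multi-run batches: one city, many agent populations.

A batch generates the environment once from a seed derived from the
master seed, then runs the model ``n_runs`` times, re-generating the
agents each run with a per-run derived seed.  Every output byte is
determined by (config, master seed).
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path

import numpy as np

from .config import SimulationConfig
from .engine import run_simulation


def derive_seed_sequences(master_seed: int, n_runs: int):
    """Environment seed plus one seed per run, all derived deterministically.

    Spawn keys keep the streams independent: key (0,) is the environment,
    key (i + 1,) is run i.
    """
    env_seq = np.random.SeedSequence(master_seed, spawn_key=(0,))
    run_seqs = [
        np.random.SeedSequence(master_seed, spawn_key=(i + 1,)) for i in range(n_runs)
    ]
    return env_seq, run_seqs


def batch_run(
    config: SimulationConfig,
    out_dir,
    n_runs: int | None = None,
) -> list[Path]:
    """Run the configured batch; returns the per-run event-log paths.

    Writes the shared environment export, one trajectory log per run and
    a ``manifest.json`` tying everything to the master seed.  On failure
    the partially written output directory is removed.
    """
    out_dir = Path(out_dir)
    n_runs = config.run.n_runs if n_runs is None else n_runs
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        env_seq, run_seqs = derive_seed_sequences(config.run.master_seed, n_runs)
        env = config.build_environment(np.random.default_rng(env_seq))
        env.save(out_dir / "environment")
        log_paths: list[Path] = []
        manifest_runs = []
        for i, seq in enumerate(run_seqs):
            log = run_simulation(config, env=env, seed=seq)
            log.metadata["run_index"] = i
            log.metadata["spawn_key"] = [i + 1]
            prefix = out_dir / f"run_{i:03d}"
            events_path, _, _ = log.save(prefix)
            log_paths.append(events_path)
            manifest_runs.append(
                {
                    "run_index": i,
                    "events": events_path.name,
                    "n_events": len(log),
                    "env_hash": log.metadata["env_hash"],
                }
            )
        manifest = {
            "master_seed": config.run.master_seed,
            "config_hash": config.content_hash(),
            "env_hash": env.content_hash(),
            "n_runs": n_runs,
            "runs": manifest_runs,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return log_paths
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise
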