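"""Flat key=value run configuration with dotted namespaces and seed fan-out.

One global seed deterministically fans out to per-stage seeds through a
recorded hash, so any pipeline stage can be re-run in isolation and
reproduce its outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

#: every recognized key with its default; unknown keys are rejected on load
DEFAULTS: dict[str, object] = {
    "seed": 0,
    "synth.n_classes": 8,
    "synth.seq_len": 40,
    "synth.n_pairs": 195,
    "synth.score_noise_sd": 0.05,
    "selex.pool_size": 2000,
    "selex.sharpness": 2.5,
    "selex.mutation_rate": 0.002,
    "selex.rounds": "3,5,7",
    "aptavae.latent_dim": 256,
    "aptavae.hidden": 256,
    "aptavae.epochs": 400,
    "aptavae.patience": 120,
    "aptavae.batch_size": 16,
    "aptavae.learning_rate": 1e-3,
    "aptavae.skip_connections": True,
    "aptavae.attention": True,
    "aptavae.use_3d": True,
    "bga.batch_size": 64,
    "bga.n_batches": 150,
    "bga.threshold": 0.9,
    "bga.convergence_tolerance": 0.01,
    "bga.convergence_window": 5,
    "library.conservation_threshold": 0.8,
    "library.forward_primer": "ACGACGCTCTTCCGATCT",
    "library.reverse_primer": "AGATCGGAAGAGCGTCGT",
    "aptaclux.latent_dim": 32,
    "aptaclux.hidden": 128,
    "aptaclux.epochs": 400,
    "aptaclux.patience": 60,
    "aptaclux.bandwidth": 0.5,
    "aptaclux.density_fraction": 0.01,
    "aptaclux.k_clusters": 10,
    "aptaclux.pca_dims": 8,
    "eval.cluster_radius": 3,
    "eval.enrichment_pseudocount": 1.0,
    "embedding.provider": "hash",
    "embedding.dim": 64,
    "embedding.seed": 0,
}


class ConfigError(ValueError):
    pass


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge DEFAULTS <- file <- overrides, rejecting unknown keys."""
    cfg = dict(DEFAULTS)
    bad = []
    if path is not None:
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"malformed line {raw!r} (expected key=value)")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in cfg:
                bad.append(key)
                continue
            cfg[key] = _coerce(val, cfg[key])
    if overrides:
        for key, val in overrides.items():
            if key not in cfg:
                bad.append(key)
                continue
            cfg[key] = _coerce(val, cfg[key]) if isinstance(val, str) else val
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(set(bad))}")
    return cfg


def _coerce(val: str, template):
    if isinstance(template, bool):
        return val.lower() in ("1", "true", "yes", "on")
    if isinstance(template, int):
        return int(val)
    if isinstance(template, float):
        return float(val)
    return val


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed (recorded in manifests); always below 2^31."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


def write_manifest(path, cfg: dict, stage: str, extra: dict | None = None) -> None:
    doc = {"stage": stage, "config": cfg, "stage_seed": stage_seed(int(cfg["seed"]), stage)}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
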