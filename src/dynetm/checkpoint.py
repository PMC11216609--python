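"""Single-archive model checkpoints with a versioned JSON manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .corpus_io import Vocabulary
from .generative import ModelParameters
from .inference import TrainConfig, VariationalState
from .losses import ClassifierHead

CHECKPOINT_VERSION = 1


def vocabulary_hash(vocabulary: Vocabulary) -> str:
    h = hashlib.sha256("\n".join(vocabulary.terms).encode("utf-8"))
    return h.hexdigest()[:16]


def save_checkpoint(path: str | Path, params: ModelParameters, state: VariationalState,
                    vocabulary: Vocabulary, config: TrainConfig | None = None,
                    seed: int | None = None) -> None:
    """Write parameters, inference networks and metadata to one npz archive."""
    path = Path(path)
    manifest = {
        "version": CHECKPOINT_VERSION,
        "K": params.n_topics, "L": params.embed_dim,
        "T": params.n_slices, "V": params.n_words,
        "eps": params.eps, "delta": params.delta, "gamma": params.gamma,
        "vocabulary_hash": vocabulary_hash(vocabulary),
        "seed": seed,
        "config": asdict(config) if config is not None else None,
        "has_eta_net": state.eta_net is not None,
        "dropout": state.dropout,
    }
    arrays = {
        "rho": params.rho, "alpha": params.alpha, "eta": params.eta,
        "vocabulary": np.asarray(vocabulary.terms, dtype=object),
    }
    arrays.update({f"net_{k}": v for k, v in state.theta_net.items()})
    arrays.update({f"head_{k}": v for k, v in state.classifier.weights.items()})
    if state.eta_net is not None:
        arrays.update({f"etanet_{k}": v for k, v in state.eta_net.items()})
    np.savez_compressed(path, manifest=json.dumps(manifest), **arrays)


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns ``(params, state, vocabulary, manifest)``."""
    with np.load(Path(path), allow_pickle=True) as z:
        manifest = json.loads(str(z["manifest"]))
        if manifest["version"] > CHECKPOINT_VERSION:
            raise ValueError(f"checkpoint version {manifest['version']} is newer than supported")
        params = ModelParameters(
            rho=z["rho"], alpha=z["alpha"], eta=z["eta"],
            eps=manifest["eps"], delta=manifest["delta"], gamma=manifest["gamma"],
        )
        theta_net = {k[4:]: z[k] for k in z.files if k.startswith("net_")}
        head = ClassifierHead({k[5:]: z[k] for k in z.files if k.startswith("head_")})
        eta_net = {k[7:]: z[k] for k in z.files if k.startswith("etanet_")} or None
        state = VariationalState(theta_net=theta_net, classifier=head, eta_net=eta_net,
                                 dropout=manifest.get("dropout", 0.1))
        vocabulary = Vocabulary(tuple(str(w) for w in z["vocabulary"]))
    if vocabulary_hash(vocabulary) != manifest["vocabulary_hash"]:
        raise ValueError("vocabulary hash mismatch in checkpoint")
    return params, state, vocabulary, manifest
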