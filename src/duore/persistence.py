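"""Checkpoint save/load for the three trained modules.

A checkpoint directory holds, per module, a ``<kind>.npz`` with the flat
parameter arrays and a shared ``meta.json`` describing tokenizer charset,
encoder configuration, schema and prompt template, so models can be rebuilt
exactly."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .datamodel import RelationSchema, SchemaEntry
from .duality import DLModel
from .encoding import CharTokenizer, EncoderConfig, SPECIALS
from .er_span import ERModel
from .rc import RCModel

__all__ = ["save_model", "load_models"]


def _charset(tokenizer: CharTokenizer) -> str:
    return "".join(sorted(t for t in tokenizer.vocab if t not in SPECIALS))


def save_model(model, kind: str, ckpt_dir: Path, tokenizer: CharTokenizer,
               enc_cfg: EncoderConfig, schema: RelationSchema, template_id: int = 5) -> None:
    ckpt_dir = Path(ckpt_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    np.savez(ckpt_dir / f"{kind}.npz", **{k: v.data for k, v in model.parameters().items()})
    meta = {
        "charset": _charset(tokenizer),
        "encoder": asdict(enc_cfg),
        "schema": [asdict(e) for e in schema.entries],
        "template_id": template_id,
    }
    (ckpt_dir / "meta.json").write_text(json.dumps(meta, ensure_ascii=False))


def load_models(ckpt_dir: Path) -> tuple[ERModel, RCModel, DLModel]:
    ckpt_dir = Path(ckpt_dir)
    meta_path = ckpt_dir / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing checkpoint metadata {meta_path}")
    meta = json.loads(meta_path.read_text())
    tokenizer = CharTokenizer(meta["charset"])
    enc_cfg = EncoderConfig(**meta["encoder"])
    schema = RelationSchema(SchemaEntry(**e) for e in meta["schema"])
    rng = np.random.default_rng(0)

    models = []
    for kind in ("er", "rc", "dl"):
        path = ckpt_dir / f"{kind}.npz"
        if not path.exists():
            raise FileNotFoundError(f"missing checkpoint {path}")
        if kind == "er":
            model = ERModel.build(tokenizer, enc_cfg, rng)
        elif kind == "rc":
            model = RCModel.build(tokenizer, enc_cfg, schema, rng)
        else:
            model = DLModel.build(tokenizer, enc_cfg, schema, rng,
                                  template_id=int(meta["template_id"]))
        with np.load(path) as npz:
            params = model.parameters()
            missing = set(params) ^ set(npz.files)
            if missing:
                raise KeyError(f"{path}: parameter mismatch on {sorted(missing)}")
            for k, p in params.items():
                p.data[...] = npz[k]
        models.append(model)
    return tuple(models)
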