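"""Saving and loading fitted identification pipelines.

A pipeline directory holds JSON metadata plus portable array containers:

    meta.json            scheme, extractor parameters, seeds, versions
    eigenfaces.{npz,json} / codebook.{npz,json}   (scheme-dependent)
    classifier.{npz,json}

Round-trips are bit-exact for the array state; the classifier is refitted
deterministically from its recorded training data, chosen parameters and
seed on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import sklearn

from . import __version__
from .classify import TrainedClassifier
from .features import (
    BowExtractor,
    Codebook,
    EigenfaceExtractor,
    EigenfaceModel,
    LBPExtractor,
    LBPSpec,
)
from .realtime import IdentificationPipeline


def save_pipeline(pipeline: IdentificationPipeline, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = pipeline.extractor
    meta: dict = {
        "scheme": ext.scheme,
        "versions": {"macaqueid": __version__, "numpy": np.__version__,
                     "sklearn": sklearn.__version__},
    }
    if isinstance(ext, EigenfaceExtractor):
        ext.model.save(out_dir / "eigenfaces")
    elif isinstance(ext, LBPExtractor):
        s = ext.spec
        meta["lbp"] = {"radius": s.radius, "neighbors": s.neighbors,
                       "grid_rows": s.grid_rows, "grid_cols": s.grid_cols,
                       "comparison": s.comparison}
    elif isinstance(ext, BowExtractor):
        ext.codebook.save(out_dir / "codebook")
        meta["bow"] = {"method": ext.method, "top_k": ext.top_k,
                       "vocabulary": ext.vocabulary, "seed": ext.seed}
    else:
        raise TypeError(f"cannot serialize extractor {type(ext).__name__}")
    pipeline.model.save(out_dir / "classifier")
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def load_pipeline(in_dir: str | Path) -> IdentificationPipeline:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "meta.json").read_text())
    scheme = meta["scheme"]
    if scheme == "EF":
        ext = EigenfaceExtractor()
        ext.model = EigenfaceModel.load(in_dir / "eigenfaces")
    elif scheme == "LBP-H":
        ext = LBPExtractor(LBPSpec(**meta["lbp"]))
    elif scheme.endswith("-BoW"):
        b = meta["bow"]
        ext = BowExtractor(b["method"], top_k=b["top_k"],
                           vocabulary=b["vocabulary"], seed=b["seed"])
        ext.codebook = Codebook.load(in_dir / "codebook")
    else:
        raise ValueError(f"unknown scheme {scheme!r} in {in_dir}")
    model = TrainedClassifier.load(in_dir / "classifier")
    return IdentificationPipeline(ext, model)
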