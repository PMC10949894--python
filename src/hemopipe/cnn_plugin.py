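"""Optional pretrained-CNN feature extraction (requires the ``cnn`` extra).

When torch and torchvision are installed, :func:`cnn_extract` runs a real
InceptionV3 / DenseNet201 forward pass and returns the pooled activations
matching the registry dimensions (2,048 and 1,920).  The core package and
its tests never import this module; the mock extractor in
:mod:`hemopipe.features` is the supported download-free surface.

``TRANSFER_HYPERPARAMS`` records the fine-tuning settings used when the
extractors are adapted to a labeled dataset before activation export.
Fine-tuning itself is out of scope here; the values are kept as plugin
configuration for fidelity.
"""

from __future__ import annotations

import numpy as np

from .features import ExtractorSpec

__all__ = ["TRANSFER_HYPERPARAMS", "cnn_extract"]

TRANSFER_HYPERPARAMS = {
    "solver": "sgdm",
    "initial_learning_rate": 1e-4,
    "validation_frequency": 30,
    "mini_batch_size": 20,
    "max_epochs": 10,
    "stride": 1,
    "dropout_rate": 0.1,
}

_LAYERS = {
    "inception_v3": ("avg_pool", 2048, 299),
    "densenet201": ("global_average_pool", 1920, 224),
}


def cnn_extract(image: np.ndarray, spec: ExtractorSpec) -> np.ndarray:
    """Pooled pretrained-CNN activations for one RGB image in [0, 1]."""
    try:
        import torch
        import torchvision.models as tvm
        import torchvision.transforms.functional as tvf
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError(
            "pretrained-CNN extraction needs the 'cnn' extra: pip install hemopipe[cnn]"
        ) from exc

    if spec.name not in _LAYERS:
        raise ValueError(f"no CNN backing for extractor {spec.name!r}")
    _, dim, side = _LAYERS[spec.name]

    x = torch.from_numpy(np.asarray(image, dtype=np.float32)).permute(2, 0, 1)
    x = tvf.resize(x, [side, side], antialias=True)
    x = tvf.normalize(x, [0.485, 0.456, 0.406], [0.229, 0.224, 0.225]).unsqueeze(0)

    if spec.name == "inception_v3":
        model = tvm.inception_v3(weights=tvm.Inception_V3_Weights.DEFAULT)
        model.fc = torch.nn.Identity()
    else:
        model = tvm.densenet201(weights=tvm.DenseNet201_Weights.DEFAULT)
        model.classifier = torch.nn.Identity()
    model.eval()
    with torch.no_grad():
        out = model(x).squeeze(0).numpy()
    assert out.shape == (dim,)
    return out
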