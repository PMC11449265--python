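"""glomil: global-local multiple-instance classification of large 3D stacks.

A two-stage weakly-supervised classifier for volumetric grayscale images
containing small objects: a cheap per-slice global network produces a
class saliency volume and a slice-count-independent top-t% prediction; a
greedy retrieval crops a handful of informative full-resolution 2D
patches while suppressing near-duplicate slices; a gated-attention local
network refines the prediction.  Trained with image-level labels only,
the saliency maps are the localization output.
"""

from .estimator import VolumeClassifier
from .io import RunConfig, Volume, load_config, read_volume, write_volume
from .phantom import PhantomSpec, generate_dataset, generate_phantom, generate_samples

__version__ = "0.1.0"

__all__ = [
    "VolumeClassifier", "RunConfig", "Volume", "load_config", "read_volume",
    "write_volume", "PhantomSpec", "generate_phantom", "generate_samples",
    "generate_dataset", "__version__",
]
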