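"""Extraction configuration for the radiomics feature bank."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

FAMILY_SIZES = {
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}
N_SHAPE = 14
N_PER_IMAGE = sum(FAMILY_SIZES.values())  # 93


@dataclass
class ExtractionConfig:
    """Knobs of the feature bank.

    bin_width
        Fixed intensity bin width for gray-level discretization, in the
        intensity units of each (possibly filtered) image; binning is
        re-anchored at the in-mask minimum of each image independently.
    log_sigmas_mm
        Laplacian-of-Gaussian scales in millimetres (converted per axis by
        the voxel spacing).
    wavelet
        Separable wavelet basis for the single-level undecimated 3D
        decomposition (8 sub-bands, letter order = filters on x, y, z).
    glcm_distance
        Chebyshev distance of co-occurrence offsets (13 unique 3D
        directions, accumulated symmetrically).
    gldm_alpha
        Dependence tolerance: a neighbour counts as dependent iff the
        absolute gray-level difference is <= alpha.
    """

    bin_width: float = 25.0
    log_sigmas_mm: tuple = (1.0, 3.0, 5.0)
    wavelet: str = "coif1"
    glcm_distance: int = 1
    gldm_alpha: int = 0
    include_log: bool = True
    include_wavelet: bool = True

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        sig = tuple(self.log_sigmas_mm)
        if any(s <= 0 for s in sig) or len(set(sig)) != len(sig):
            raise ValueError("LoG sigmas must be positive and unique")
        self.log_sigmas_mm = sig

    @property
    def image_types(self) -> list:
        """Ordered image-type names ('original', LoG scales, wavelet bands)."""
        out = ["original"]
        if self.include_log:
            for s in self.log_sigmas_mm:
                out.append("log-sigma-%s-mm-3D" % str(float(s)).replace(".", "-"))
        if self.include_wavelet:
            out.extend("wavelet-%s" % b for b in WAVELET_SUBBANDS)
        return out

    @property
    def n_features(self) -> int:
        return N_SHAPE + len(self.image_types) * N_PER_IMAGE

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
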