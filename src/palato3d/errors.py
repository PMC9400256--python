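"""Exception hierarchy shared by all pipeline stages."""


class Palato3DError(Exception):
    """Base class for all package errors."""


class ValidationError(Palato3DError):
    """Invalid configuration or input values (fail-fast, before compute)."""


class MeshFormatError(Palato3DError):
    """A mesh file could not be parsed as the named format.

    Parameters
    ----------
    path : str
        Offending file.
    offset : int
        Best-effort byte offset where parsing failed (0 when unknown).
    """

    def __init__(self, path, offset=0, detail=""):
        self.path = str(path)
        self.offset = int(offset)
        super().__init__(
            f"cannot parse {self.path!r} (byte offset {self.offset}): {detail}"
        )


class EmptyMeshError(Palato3DError):
    """Mesh has no vertices or no faces."""


class EmptySegmentationError(Palato3DError):
    """Thresholding produced an all-background mask."""


class DegenerateConfigurationError(Palato3DError):
    """Landmark configuration insufficient for a rigid fit (<3 pairs or collinear)."""


class NonConvergenceError(Palato3DError):
    """ICP correspondence collapse or failure to converge."""


class ProjectionError(Palato3DError):
    """Landmark/sulcus samples lie too far from the mesh surface."""


class OrientationError(Palato3DError):
    """Posterior border samples are anterior to the molar landmarks."""


class OrderingError(Palato3DError):
    """ROI boundary landmarks are not in anterior->posterior order."""


class DegenerateSampleError(Palato3DError):
    """All paired differences are zero: the signed-rank p-value is undefined."""
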