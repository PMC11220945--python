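"""Exception hierarchy shared by all mlpscore modules."""


class MlpScoreError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(MlpScoreError):
    """Voxel geometry is incompatible with the requested operation."""


class ConsistencyError(MlpScoreError):
    """An atlas/volume pair or sidecar table is internally inconsistent."""


class ValidationError(MlpScoreError):
    """Input values violate a documented contract."""


class MissingOutcomeError(ValidationError):
    """No CPC assessment is available for a patient who needs one."""


class UnknownRoiError(MlpScoreError, KeyError):
    """A roi_id does not exist in the atlas under consideration."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)
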