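"""Device error contract.

The screening device reports exactly six user-facing error conditions.
Their message strings are part of the device interface and must be
reproduced byte-for-byte (including the en dash in the QC failure
message), so they live here as module constants.
"""

MSG_TISSUE_SITE = "Non-qualifying tissue site."
MSG_DISEASE_STAGE = "Non-qualifying disease stage."
MSG_UNSUPPORTED = "Unsupported or missing image file."
MSG_CORRUPTED = "Corrupted image file."
MSG_MAGNIFICATION = "Required magnification unavailable."
MSG_QC_FAILURE = "QC Failure – Insufficient tissue tiles."

ALL_DEVICE_MESSAGES = (
    MSG_TISSUE_SITE,
    MSG_DISEASE_STAGE,
    MSG_UNSUPPORTED,
    MSG_CORRUPTED,
    MSG_MAGNIFICATION,
    MSG_QC_FAILURE,
)


class HistoscreenError(Exception):
    """Base class for all package errors."""


class DeviceError(HistoscreenError):
    """An error with one of the six user-facing device messages.

    ``message`` is the exact string shown to the clinician.
    """

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message


class MetadataError(DeviceError):
    """Tissue site / disease stage gate failed."""


class UnsupportedImageError(DeviceError):
    def __init__(self):
        super().__init__(MSG_UNSUPPORTED)


class CorruptedImageError(DeviceError):
    def __init__(self):
        super().__init__(MSG_CORRUPTED)


class MagnificationError(DeviceError):
    def __init__(self):
        super().__init__(MSG_MAGNIFICATION)


class InsufficientTissueError(DeviceError):
    """No tile survived the QC score filter."""

    def __init__(self):
        super().__init__(MSG_QC_FAILURE)
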