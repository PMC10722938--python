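"""Exception hierarchy for kneevbr."""


class KneeVBRError(Exception):
    """Base class for all kneevbr errors."""


class GeometryError(KneeVBRError):
    """Invalid or conflicting phantom geometry (e.g. overlapping shells)."""


class GridMismatchError(KneeVBRError):
    """Volumes expected on the same grid differ in shape or spacing."""


class RegistrationError(KneeVBRError):
    """Registration optimization failed or diverged."""


class DesignError(KneeVBRError):
    """Statistical design matrix is invalid (rank-deficient, too few rows...)."""
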