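"""Typed exceptions raised across the pipeline."""


class MedimrError(Exception):
    """Base class for all package errors."""


class ValidationError(MedimrError):
    """Input table or configuration violates a hard contract."""


class NoInstrumentsError(MedimrError):
    """No usable instruments remain for an exposure-outcome pair."""

    def __init__(self, exposure_id: str, outcome_id: str, stage: str = ""):
        self.exposure_id = exposure_id
        self.outcome_id = outcome_id
        self.stage = stage
        msg = f"no instruments remain for exposure {exposure_id!r} on outcome {outcome_id!r}"
        if stage:
            msg += f" (stage: {stage})"
        super().__init__(msg)


class InsufficientSnpsError(MedimrError):
    """An estimator or diagnostic needs more SNPs than are available."""

    def __init__(self, method: str, needed: int, got: int):
        self.method = method
        self.needed = needed
        self.got = got
        super().__init__(f"{method} needs at least {needed} SNPs, got {got}")


class UndefinedProportionError(MedimrError):
    """Mediated proportion is undefined because the total effect is zero."""
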