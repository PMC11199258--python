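"""Exception hierarchy shared by the neoscr pipeline."""


class NeoscrError(Exception):
    """Base class for all neoscr errors."""


class ValidationError(NeoscrError):
    """Malformed or internally inconsistent input data."""


class ReferenceRangeError(NeoscrError):
    """A postnatal day fell outside the coverage of the reference table."""

    def __init__(self, day, day_range, patient_id=None):
        self.day = day
        self.day_range = day_range
        self.patient_id = patient_id
        who = f" for patient {patient_id!r}" if patient_id is not None else ""
        super().__init__(
            f"postnatal day {day}{who} is outside the reference table coverage "
            f"[{day_range[0]}, {day_range[1]}]; extrapolation is never done silently"
        )


class CollinearityError(NeoscrError):
    """Two exposure indicators are identical across every row of a design."""


class ConvergenceError(NeoscrError):
    """A mixed-model fit failed to converge even after the fallback ladder."""
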