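"""Exception hierarchy.

All wardflow exceptions derive from :class:`WardflowError` so callers can
catch the package's failures with a single clause.  Validation-style
entry points (``validate_process``, ``load_scenario``) report rule
violations as data; exceptions are reserved for contract breaches.
"""

from __future__ import annotations


class WardflowError(Exception):
    """Base class for all wardflow errors."""


class MalformedProcess(WardflowError):
    """The BPMN document violates the supported subset or its invariants."""


class UnresolvedBranch(WardflowError):
    """An exclusive split has no applicable branch choice for a group."""


class UnknownArea(WardflowError):
    """An area id is not present in the hospital configuration."""


class UnknownTarget(WardflowError):
    """A modifier references an area/resource-type/pair that does not exist."""


class NonPositiveEfficiency(WardflowError):
    """Efficiency percentages must be strictly positive."""


class CountMismatch(WardflowError):
    """Arrival-window counts do not sum to the requested cohort size."""


class UnclassifiedPatient(WardflowError):
    """An AIS profile matches no configured injury-group signature."""


class AttachNotAttachable(WardflowError):
    """An attach demand targets a type that cannot stay with a patient."""


class DetachNotAttached(WardflowError):
    """A detach demand fired for a patient with no such attached instance."""


class InvalidScenario(WardflowError):
    """A scenario's cross-references or preconditions do not hold."""


class MissingBaseline(WardflowError):
    """An indicator computation met a group with no baseline entry."""


class ConfigError(WardflowError):
    """Raised by the config loader with *all* violations collected.

    Attributes
    ----------
    violations : list of str
        Every reference or schema problem found, not just the first.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
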