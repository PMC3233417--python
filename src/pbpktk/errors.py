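"""Exception hierarchy for the toolkit."""


class PBPKError(Exception):
    """Base class for all toolkit errors."""


class StructureError(PBPKError):
    """A model structure is internally inconsistent (unknown compartment,
    flows that do not close, missing gas exchange where required)."""


class ParameterError(PBPKError):
    """A chemical or physiological parameter is missing or out of range."""


class ScenarioError(PBPKError):
    """An exposure scenario violates its invariants."""


class SolverError(PBPKError):
    """Numerical integration failed.

    Carries ``time_h``, the simulation time at which the failure occurred.
    """

    def __init__(self, message: str, time_h: float | None = None):
        super().__init__(message)
        self.time_h = time_h


class UnitError(PBPKError):
    """Two quantities with incompatible unit tags were combined."""


class DataError(PBPKError):
    """An observed dataset or biomonitoring table violates its invariants."""


class ConfigError(PBPKError):
    """A configuration document failed validation.

    ``problems`` lists every violation found, not just the first.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))
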