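"""Exception hierarchy shared across the pipeline."""


class PdregioError(Exception):
    """Base class for all package errors."""


class InputError(PdregioError):
    """Malformed user input (unparseable SMILES/MOL, bad scenario token...)."""


class DomainError(PdregioError):
    """Chemically meaningless request (no aromatic C-H sites, no stable
    intermediates for either mechanism, empty energy map)."""


class ConfigurationError(PdregioError):
    """Invalid or incomplete run configuration (e.g. Pd present but no metal
    basis set assigned)."""


class TableKeyError(PdregioError, LookupError):
    """A (substrate, mechanism, h_label) key is absent from an EnergyTable."""


class ContractError(PdregioError):
    """An object violates a stage precondition (e.g. an intermediate reaches
    the geometry filter without a Pd-C distance)."""


class NumericError(PdregioError):
    """Degenerate numerical input (zero-norm displacement mode)."""
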