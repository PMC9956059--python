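"""Exception hierarchy shared across the pipeline."""


class CrossScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(CrossScreenError):
    """A configuration value violates its contract; names the offending field."""


class VcfParseError(CrossScreenError):
    """Malformed VCF input; carries positional diagnostics where available."""


class FormatError(CrossScreenError):
    """A file is structurally valid but missing a required feature (e.g. GT)."""


class ManifestError(CrossScreenError):
    """Sample-group manifest is inconsistent with the data or the screen."""


class FixtureIntegrityError(CrossScreenError):
    """A packaged fixture does not match its recorded checksum."""


class PedigreeError(CrossScreenError):
    """A pedigree references an unknown individual or is cyclic."""


class RejectionError(CrossScreenError):
    """Conditional resampling exceeded its retry cap."""


class HgvsParseError(CrossScreenError):
    """Text does not match the supported HGVS substitution grammar."""


class ReferenceMismatchError(CrossScreenError):
    """A variant's REF base disagrees with the reference sequence."""


class GeneModelError(CrossScreenError):
    """A gene model violates its invariants (CDS phase, interval order)."""


class JoinError(CrossScreenError):
    """Two keyed tables do not cover the same sites; lists orphans."""


class EnrichmentDomainError(CrossScreenError):
    """Hypergeometric parameters outside their domain, or empty universe."""


class StageError(CrossScreenError):
    """A pipeline stage failed; carries the stage name and cause."""
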