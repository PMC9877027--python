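"""Exception hierarchy for the mycoroot pipeline."""


class MycorootError(Exception):
    """Base class for all mycoroot errors."""


class ConfigurationError(MycorootError, ValueError):
    """Inconsistent user configuration (bounds, class sets, proportions)."""


class DimensionError(MycorootError, ValueError):
    """Raster shape incompatible with a requested block operation."""


class AlignmentError(MycorootError, ValueError):
    """Rasters do not share grid shape, origin or pixel size."""


class DomainError(MycorootError, ValueError):
    """A numeric argument falls outside its mathematical domain."""


class DataError(MycorootError, ValueError):
    """Input table values violate the documented contract."""


class MissingDataError(MycorootError, ValueError):
    """A required subset of the input data is entirely absent."""


class ContractError(MycorootError, ValueError):
    """Two pipeline artifacts that must agree (e.g. unit ids) do not."""
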