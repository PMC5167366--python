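"""Exception hierarchy for gsknet."""


class GsknetError(Exception):
    """Base class for all gsknet errors."""


class MetaModelError(GsknetError):
    """A graph element refers to a vocabulary entry that does not exist,
    or the vocabulary itself is inconsistent (duplicate ids, dangling
    parents, cyclic hierarchies)."""


class GraphError(GsknetError):
    """Structural violation of the knowledge graph (dangling endpoints,
    unknown concept ids)."""


class ParseError(GsknetError):
    """A reader could not interpret its input file."""


class TableSpecError(GsknetError):
    """A declarative table import specification is invalid or does not
    match the table it is applied to."""


class ExportError(GsknetError):
    """A graph could not be serialised."""


class CollapseError(GsknetError):
    """An equal-relation component links concepts of different classes
    and cannot be collapsed."""


class WorkflowError(GsknetError):
    """A workflow document is invalid or a step failed."""
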