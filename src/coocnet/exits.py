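"""Termination codes for the reconstruction/expansion loop."""

from __future__ import annotations

from enum import Enum


class ExitCode(str, Enum):
    """Why a run stopped. Every run terminates with exactly one code."""

    INPUT_TOO_SMALL = "input_too_small"          # fewer than three PMIDs submitted
    NO_ENTITIES = "no_entities"                  # nothing to mine in any document
    EMPTY_GRAPH = "empty_graph"                  # no statistically significant co-occurrence
    NO_CLIQUES_OR_SINGLE_COMMUNITY = "no_cliques_or_single_community"
    NO_CONNECTING_PATH = "no_connecting_path"    # no community-connecting tour
    NO_NEW_PMIDS = "no_new_pmids"                # queries matched nothing new
    CONVERGED_SINGLE_COMPONENT = "converged_single_component"
    MAX_ITERATIONS = "max_iterations"            # safety cap on the loop


class ExitSignal(Exception):
    """Raised by pipeline stages to terminate the run with a code."""

    def __init__(self, code: ExitCode, message: str = "") -> None:
        super().__init__(message or code.value)
        self.code = code
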