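"""cgr: reconstruction and mechanistic classification of complex
chromosomal insertions from breakpoint junctions and copy-number profiles.

The package covers the full desk workflow: simulating rearranged
derivative chromosomes under replicative template-switching or end-joining
models, annotating breakpoint-junction signatures (microhomology,
untemplated and templated insertions), segmenting probe-level copy-number
data, reconstructing derivative chromosomes through a breakpoint graph
with minimal hypothetical-junction inference, classifying the generative
mechanism, and predicting the meiotic transmission of parental insertions.
"""

__version__ = "0.1.0"

from .core import (  # noqa: F401
    BreakEnd,
    CNVCall,
    DerivativeModel,
    GenomeRef,
    Junction,
    JunctionFeature,
    SegmentCN,
    calls_from_segments,
    closed_length,
    revcomp,
)
from .genome import make_toy_genome  # noqa: F401
from .simulate import (  # noqa: F401
    EventChain,
    SwitchEvent,
    TruthModel,
    emit_junction_reads,
    emit_probe_table,
    make_end_joining_case,
    make_replicative_case,
    simulate_end_joining_insertion,
    simulate_replicative,
)
from .annotate import (  # noqa: F401
    AnnotationConfig,
    annotate_junction,
    annotate_reads,
    classify_insert,
    locate_breakends,
    measure_microhomology,
)
from .cnv import (  # noqa: F401
    call_cnvs,
    detect_dup_trp_inv_dup,
    pattern_string,
    segment_probes,
)
from .reconstruct import (  # noqa: F401
    build_graph,
    count_junctions,
    emit_derivative_sequence,
    reconstruct,
)
from .classify import (  # noqa: F401
    CaseFeatures,
    ClassifierThresholds,
    MechanismCall,
    annotate_repeats,
    classify,
    extract_features,
)
from .inheritance import (  # noqa: F401
    ParentalGenotype,
    enumerate_crossovers,
    enumerate_segregation,
    match_child,
)
from .fixtures import list_cases, load_fixture, run_case  # noqa: F401


def cohort_incidence(n_tested: int, n_events: int) -> float:
    """Incidence expressed as '1 in N individuals tested'.

    38,000 individuals with 76 insertion carriers gives 1 in 500.
    """
    if n_events <= 0 or n_tested <= 0:
        raise ValueError("counts must be positive")
    return n_tested / n_events
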