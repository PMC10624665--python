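"""ipqc: quality control, curation and antigen prioritization for MHC
class I immunopeptidomics datasets."""

__version__ = "0.1.0"

from .peptidome_io import (  # noqa: F401
    PeptideRecord,
    ProteinDb,
    SampleRun,
    normalize_allele,
    read_fasta,
    read_peptide_table,
)
from .binding_predictor import (  # noqa: F401
    BindingPrediction,
    PssmModel,
    PssmPredictor,
    RankCalibration,
    build_pssm,
    calibrate_ranks,
    score_peptide,
)
from .contaminant_filter import (  # noqa: F401
    CoverageRatioResult,
    CutoffCalibration,
    calibrate_cutoff,
    flag_and_clean,
    protein_coverage_ratio,
)
from .candidate_selection import (  # noqa: F401
    CandidateCriteria,
    CandidateRow,
    export_polyk,
    replicate_count,
    select_candidates,
)
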