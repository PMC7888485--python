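"""Edge retention consistency under proportional thresholding.

Thresholds each subject-session connectome independently at 20 retained
proportions (1.00 down to 0.05) and asks, per edge: of the subjects in
which the edge survived at least once, in how many did it survive in both
sessions?  The median of this consistency ratio falls steadily as
thresholding tightens (Spearman rho ~ -1 against stringency): independent
thresholding of the two sessions keeps different edges.
"""

import numpy as np

from connrel import CohortSpec, generate_timeseries_cohort, threshold_sweep
from connrel.cohort import SESSIONS
from connrel.connectome import build_edge_panel, correlation_matrix
from connrel.preprocess import preprocess_session

cohort = generate_timeseries_cohort(
    CohortSpec(n_subjects=40, n_regions=20, n_timepoints_per_run=600, seed=3)
)
matrices = {s: [] for s in SESSIONS}
for subject in cohort.subjects:
    for session in SESSIONS:
        ts = preprocess_session(subject.sessions[session], gsr=False)
        matrices[session].append(
            correlation_matrix(ts, subject.subject_id, session)
        )

report = threshold_sweep(
    build_edge_panel(matrices[1]), build_edge_panel(matrices[2]),
    mode="relative", min_subjects=5,
)
print("retained proportion -> median consistency ratio")
for p, med in zip(report.thresholds, report.consistency_median):
    print(f"  {p:4.2f}  ->  {med:.3f}")
print(f"trend vs stringency: Spearman rho = {report.trend_consistency_rho:.3f},"
      f" p = {report.trend_consistency_p:.2g}")
print("the ratio declines monotonically: stricter thresholds retain")
print("increasingly session-specific edge sets")
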