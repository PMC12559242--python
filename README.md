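# splicewalk

Network-diffusion imputation of percent-spliced-in (PSI) values for
alternative-splicing events in single-cell RNA-seq.

## The problem

Alternative splicing can be quantified per cell from split reads crossing
splice junctions: for an event *e* with inclusion junctions *IJC* and
exclusion junctions *EJC*,

    PSI_raw(c, e) = mean_{j in IJC} RC(c, j)
                    ------------------------------------------------
                    mean_{j in IJC} RC(c, j) + mean_{j in EJC} RC(c, j)

where RC are library-size-normalized junction read counts.  At single-cell
depth these matrices are extremely sparse: many event-cell pairs have no
junction reads at all, so the raw PSI (set to 0 by convention for such
pairs) is a poor estimate.  `splicewalk` recovers PSI by borrowing
information from similar cells and similar events.

## The method

1. **Cell similarity.**  Cells with similar splicing-machinery activity
   have similar splicing.  From RNA-binding-protein (RBP) expression (or
   raw junction counts, or raw PSI), the feature matrix is PCA-reduced to
   0.9 cumulative explained variance, pairwise Euclidean distances are
   computed, and each cell's neighbor count k_c is chosen by a *dynamic-K*
   jump detector on its sorted distance profile.  The k_c nearest distances
   pass through a Gaussian kernel exp(−(d/σ_c)²) with adaptive bandwidth
   σ_c = d_(⌈k_c/3⌉+1), and the matrix is symmetrized (S ← S + Sᵀ).
2. **Event similarity.**  A normalized-Euclidean distance over a sequence
   feature embedding is fused with a normalized-Euclidean distance over
   RBP-regulation profiles (Pearson correlations of event PSI with RBP
   expression).  The fusion weight ω(p) = 1/(1 + e^{ap+b}) with
   a = −2·ln 9999, b = ln 9999 depends on the p-value of the correlation
   between the two events' regulation profiles.  A fixed k_event = 10
   kernel gives the event network.
3. **Diffusion.**  Both networks are row-normalized and diffused by a
   random walk with restart, V ← (1−λ)·V·S̃ + λ·V⁰ (λ = 0.2), stopped when
   the relative change SSE/SST between iterates drops below 0.05, then
   re-sparsified to the original top-k per row and renormalized.
4. **Three imputation strategies.**  (1) smooth the PSI matrix with the
   diffused cell network; (2) smooth the inclusion/exclusion count
   matrices and recompute the PSI ratio; (3) smooth the strategy-2 PSI
   across similar events.  Each is iterated to a fixed point under the same
   SSE/SST stopping rule.
5. **Dropout scenarios.**  Each event-cell pair is classified: observed
   PSI strictly inside (0,1) is non-dropout (ND); the rest carry dropout,
   split by two logistic regressions into biological dropout (BD, the cell
   truly expresses one isoform), technical dropout with neighborhood
   information (TD+Info), and without (TD−Info).  Features summarize
   junction reads and PSI in the target cell and its network neighbors.
6. **Combination.**  The final estimate blends the strategies with the
   scenario probabilities as coefficients:

       PSI = P_ND⊙S1 + (1−P_ND)⊙(P_BD⊙S2 + (1−P_BD)⊙(P_TD+Info⊙S2
             + (1−P_TD+Info)⊙S3))

A synthetic-data generator (`splicewalk.simulation`) emulates cell groups
with group-specific true PSI, RBP expression linearly coupled to PSI,
library-size variation, and the four observation scenarios, providing
ground truth for every quantity; `splicewalk.evaluation` implements the
scoring statistics (per-cell Spearman correlation, per-event RMSE,
recall-weighted accuracy score, benchmark-event filters, differential
splicing ROC/AUC, clustering NMI).

## Worked example

```bash
splicewalk simulate --out data/ --cells 30 --events 40 --seed 5
splicewalk impute --data data/ --out run/ --seed 5
splicewalk evaluate --data data/ --imputed run/ --out metrics.json
```

The evaluate step prints (numbers from this exact command sequence):

```json
{
  "psi_raw": {
    "mean_abs_error": 0.1919311419302276,
    "median_scc": 0.6450984990619137,
    "median_rmse": 0.3033639456245219,
    "nmi": 1.0
  },
  "psi_final": {
    "mean_abs_error": 0.08679984660811618,
    "median_scc": 0.9195121951219511,
    "median_rmse": 0.12096293355182572,
    "nmi": 1.0
  }
}
```

The raw PSI misestimates the truth by 0.19 on average (30% of pairs are
simulated dropouts whose raw PSI is 0); after imputation the mean error
drops to 0.09, the median per-cell Spearman correlation with the truth
rises from 0.65 to 0.92, and the per-event RMSE falls from 0.30 to 0.12.
Both profiles cluster the three simulated cell groups perfectly here
(NMI 1.0); on noisier real data the raw profile typically does not.

The same pipeline is available from Python via
`splicewalk.impute_dataset(...)`, which accepts in-memory count matrices,
an event table, RBP expression, and either training labels or pre-trained
scenario models (optionally fine-tuned against a conserved-event
reference).

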