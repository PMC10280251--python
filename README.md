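# ecgiva — ECG artifact removal by independent vector analysis

Surface ECG is routinely contaminated by baseline wander (respiratory and
body-movement drift), electrode-motion transients and muscle (EMG) noise.
These artifacts overlap the ECG band, so they cannot be filtered out; they
can, however, be *separated* out, because a multichannel recording is close
to a linear mixture of statistically independent sources.

`ecgiva` is a toolkit for doing that with **independent vector analysis
(IVA)** — joint blind source separation of a recording and its delayed
copies — and for benchmarking it against the classic single-set baselines.
It is aimed at biomedical-signal researchers who want a reproducible,
seeded Monte-Carlo harness rather than a one-off script.

## The model

A K-channel recording and its delayed copies form D data sets
`X^d = A^d S^d + N^d`.  The k-th estimated source across data sets is a
*source component vector* (SCV) `y_k = (y_k^1, …, y_k^D)`; IVA finds
un-mixing matrices `W^d` (with `Y^d = W^d X^d`) by minimising the mutual
information between SCVs,

    I_IVA = Σ_k ( Σ_d H[y_k^d] − I[y_k] ) − Σ_d log|det W^d| + const,

realised through an SCV prior: multivariate Gaussian (**IVA-G**,
second-order statistics only), multivariate Laplacian (**IVA-L**,
higher-order only), or generalized Gaussian (**IVA-GGD**, both; shape β
estimated per SCV by kurtosis matching).  **FastICA** and **CCA-BSS**
(lag-1 autocorrelation eigendecomposition) are included as baselines.

Separation quality is scored on `G^d = W^d A^d` via the joint
inter-symbol-interference index `ISI_com` ∈ [0, 1] (0 = ideal), the
column-leakage index `U` (0 = ideal), and the relative ECG reconstruction
error `CRMSE = RMS(s_ECG − y_ECG)/RMS(s_ECG)` after permutation/sign/scale
alignment.  See `docs/methods.md` for the full model, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from ecgiva import (AlgorithmOptions, RecordingBundle, make_source_set,
                    make_datasets, iva_g, global_matrix, isi_com, u_wa,
                    denoise, crmse)

# four sources (ECG, BW, EM, MA) at 360 Hz, mixed through random 4x4
# matrices into D=4 delayed data sets with 20 dB sensor noise
src = make_source_set(fs=360.0, duration=10.0, heart_rate=72.0, seed=5)
coll = make_datasets(src, delays=(0, 1, 2, 3), snr_db=20.0, mixing_seed=5)

res = iva_g(coll, AlgorithmOptions(seed=5))
G = global_matrix(res.W, coll.mixing)
print(f"ISI_com = {isi_com(G):.3f}   U = {u_wa(G):.3f}   iterations = {res.n_iterations}")

# end-to-end de-noising of the (simulated) recording
rec = RecordingBundle(coll.mixed[0], 360.0, [f"lead{i+1}" for i in range(4)])
cleaned, report = denoise(rec, "iva_g")
print(f"selected component = {report.selected}, QRS scores = {np.round(report.scores, 3)}")
truth = coll.datasets[0].sources[0][: cleaned.size]
y = cleaned - cleaned.mean(); s = truth - truth.mean()
print(f"CRMSE(cleaned ECG) = {crmse(s, (y @ s / (y @ y)) * y):.3f}")
```

prints

```
ISI_com = 0.229   U = 2.811   iterations = 512
selected component = 3, QRS scores = [0.011 0.125 0.02  0.38 ]
CRMSE(cleaned ECG) = 0.351
```

Reading the numbers: `ISI_com = 0.229` says the 4×4 global matrix is
diagonal-dominant but with visible leakage — at 10 s blocks the smooth
artifacts expose few effective degrees of freedom, which bounds how well
*any* separator can pin them (the Monte-Carlo mean over mixing draws at
these conditions is ≈ 0.2; on controlled sources that satisfy the model's
identifiability conditions the same optimiser reaches ISI < 0.01).  The
QRS-periodicity score picked component 3 as the ECG, and the cleaned trace
tracks the true ECG with a relative RMS error of 0.35, versus ≈ 0.9 for the
best raw electrode.

The same pipeline is scriptable from the shell:

```sh
ecgiva simulate --duration 10 --snr 20 --seed 5 --out demo        # CSV + npz
ecgiva denoise demo_mixed.csv --algorithm iva_g --out clean.csv   # cleaned ECG
ecgiva table 2 --reps 20 --seed 1                                 # SNR-sweep table
```

Real recordings in WFDB format (MIT-BIH family, signal formats 16/212) are
read with `ecgiva.read_wfdb`; plain CSV matrices with `read_csv_matrix`.

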