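# Cohort presets for the synthetic dynamic-PET simulator.
#
# Each group template gives, per region, the mean and SD of the ground-truth
# non-displaceable binding potential (bpnd) and of the relative delivery
# (r1, flow relative to healthy cerebellum). Subjects draw their regional
# kinetics from these distributions (bpnd clipped at 0, r1 at 0.1), with
# regional deviations correlated within a subject: amyloid burden and
# global perfusion are subject-level traits.
#
# The templates encode the qualitative regional signatures of the dementia
# groups: AD-like — high cortical amyloid binding (occipital least) with a
# mild frontal/parietal flow deficit; DLB-like — heterogeneous modest
# binding with a posterior-dominant (occipital/parietal) flow deficit;
# FTLD-like — no specific binding beyond the healthy background but a
# marked frontal flow deficit; MCI-like — an attenuated, more variable AD
# pattern; HC — a low-binding background whose positive tail reflects
# incidental amyloid positivity in elderly controls, and normal flow.
# White matter carries a small non-specific retention and lower perfusion
# in every group. Magnitudes are simulator presets chosen to be
# physiologically plausible, not measured values.

default_n:
  AD: 16
  DLB: 8
  FTLD: 5
  MCI: 5
  HC: 29

groups:
  HC:
    FL:   {bpnd_mean: 0.12, bpnd_sd: 0.30, r1_mean: 1.00, r1_sd: 0.15}
    PL:   {bpnd_mean: 0.12, bpnd_sd: 0.30, r1_mean: 1.00, r1_sd: 0.15}
    TL:   {bpnd_mean: 0.12, bpnd_sd: 0.30, r1_mean: 1.00, r1_sd: 0.15}
    OL:   {bpnd_mean: 0.12, bpnd_sd: 0.30, r1_mean: 1.00, r1_sd: 0.15}
    WM:   {bpnd_mean: 0.20, bpnd_sd: 0.10, r1_mean: 0.45, r1_sd: 0.05}
    CERB: {bpnd_mean: 0.00, bpnd_sd: 0.03, r1_mean: 1.00, r1_sd: 0.15}

  AD:
    FL:   {bpnd_mean: 0.70, bpnd_sd: 0.45, r1_mean: 0.88, r1_sd: 0.15}
    PL:   {bpnd_mean: 0.70, bpnd_sd: 0.45, r1_mean: 0.88, r1_sd: 0.15}
    TL:   {bpnd_mean: 0.65, bpnd_sd: 0.45, r1_mean: 0.93, r1_sd: 0.15}
    OL:   {bpnd_mean: 0.42, bpnd_sd: 0.36, r1_mean: 0.97, r1_sd: 0.15}
    WM:   {bpnd_mean: 0.25, bpnd_sd: 0.10, r1_mean: 0.43, r1_sd: 0.05}
    CERB: {bpnd_mean: 0.00, bpnd_sd: 0.03, r1_mean: 1.00, r1_sd: 0.15}

  DLB:
    FL:   {bpnd_mean: 0.35, bpnd_sd: 0.40, r1_mean: 0.90, r1_sd: 0.15}
    PL:   {bpnd_mean: 0.35, bpnd_sd: 0.40, r1_mean: 0.80, r1_sd: 0.15}
    TL:   {bpnd_mean: 0.30, bpnd_sd: 0.35, r1_mean: 0.85, r1_sd: 0.15}
    OL:   {bpnd_mean: 0.28, bpnd_sd: 0.35, r1_mean: 0.75, r1_sd: 0.15}
    WM:   {bpnd_mean: 0.22, bpnd_sd: 0.10, r1_mean: 0.43, r1_sd: 0.05}
    CERB: {bpnd_mean: 0.00, bpnd_sd: 0.03, r1_mean: 1.00, r1_sd: 0.15}

  FTLD:
    FL:   {bpnd_mean: 0.12, bpnd_sd: 0.30, r1_mean: 0.72, r1_sd: 0.15}
    PL:   {bpnd_mean: 0.12, bpnd_sd: 0.30, r1_mean: 0.92, r1_sd: 0.15}
    TL:   {bpnd_mean: 0.12, bpnd_sd: 0.30, r1_mean: 0.90, r1_sd: 0.15}
    OL:   {bpnd_mean: 0.12, bpnd_sd: 0.30, r1_mean: 1.00, r1_sd: 0.15}
    WM:   {bpnd_mean: 0.20, bpnd_sd: 0.10, r1_mean: 0.45, r1_sd: 0.05}
    CERB: {bpnd_mean: 0.00, bpnd_sd: 0.03, r1_mean: 0.95, r1_sd: 0.15}

  MCI:
    FL:   {bpnd_mean: 0.45, bpnd_sd: 0.45, r1_mean: 0.93, r1_sd: 0.15}
    PL:   {bpnd_mean: 0.45, bpnd_sd: 0.45, r1_mean: 0.93, r1_sd: 0.15}
    TL:   {bpnd_mean: 0.42, bpnd_sd: 0.45, r1_mean: 0.94, r1_sd: 0.15}
    OL:   {bpnd_mean: 0.25, bpnd_sd: 0.30, r1_mean: 0.98, r1_sd: 0.15}
    WM:   {bpnd_mean: 0.22, bpnd_sd: 0.10, r1_mean: 0.44, r1_sd: 0.05}
    CERB: {bpnd_mean: 0.00, bpnd_sd: 0.03, r1_mean: 1.00, r1_sd: 0.15}
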