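# vepasl

Vessel-encoded multi-PLD arterial spin labeling (ASL) analysis for
quantifying **collateral perfusion** in acute ischemic stroke.

## The problem

In acute stroke, tissue downstream of an occluded artery can stay alive on
*collateral* blood flow arriving from other feeding arteries.
Vessel-encoded pseudo-continuous ASL (VEPCASL) spatially modulates the
labeling efficiency across the neck so the perfusion signal of the four
brain-feeding arteries — the right/left internal carotid arteries (ICAs)
and the right/left vertebral arteries (VAs) — can be separated in every
voxel. Acquiring the encoded series at multiple post-labeling delays (PLDs)
additionally resolves the arterial transit time (ATT). This package
implements the full analysis chain for such data:

1. **Protocol / encoding** (`vepasl.protocol`) — a 1.4 s labeling train, six
   nominal PLDs (0.25–1.5 s; effective 0.79–2.04 s once the 1085 ms
   multi-slice readout is accounted for), eight encoding cycles (control,
   label, 2× left–right, 2× anterior–posterior, 2× diagonal) giving 96
   volumes. The encoding matrix `W` holds per-cycle, per-artery labeling
   efficiencies `w_ea ∈ [−1, +1]`.
2. **Decoding** (`vepasl.decode`) — each voxel's encoded measurements follow
   `S_e = static − Σ_a (1 − w_ea)·ΔM_a`. A maximum a posteriori search over
   sparse artery-support classes (empty set, singletons, pairs) selects the
   feeding arteries and their difference signals `ΔM_a` at every PLD.
3. **Kinetic model fitting** (`vepasl.kinetic`, `vepasl.fit`) — the general
   ASL kinetic model
   `ΔM(t) = 2 M0b α (f/6000) T1′ e^{−Δt/T1b} (1 − e^{−(t−Δt)/T1′})`
   (inflow phase; exponential decay after the bolus) is fitted per artery
   for absolute cerebral blood flow `f` (CBF, ml/100 g/min) and transit time
   `Δt` (ATT, s), with `M0b` calibrated from the CSF signal.
4. **Derived maps and ROIs** (`vepasl.maps`) — **Direct CBF** (flow from the
   ipsilateral ICA), **Indirect CBF** (flow from all other arteries — the
   collateral measure), the CBF-weighted ATT, an ADC-thresholded
   (< 620×10⁻⁶ mm²/s) ischemic core, and spherical-shell ROIs:
   *Surviving tissue* (10 mm shell around the final infarct) and *Peri-core*
   (20 mm shell around the core), with mirrored contralateral equivalents,
   all restricted to gray matter (partial volume > 0.5).
5. **Statistics** (`vepasl.stats`) — tissue-survival fractions across
   10 ml/100 g/min Indirect-CBF bins (excluding voxels with Direct CBF
   > 25), a pooled two-proportion z-test above/below 25 ml/100 g/min, and
   patient-level two-way ANOVAs (ROI × timepoint) of the Indirect-CBF
   fraction and mean weighted ATT.

Because patient data of this kind cannot be redistributed, the package
ships a **digital phantom** (`vepasl.phantom`) that synthesizes the full
input set — encoded 4D series, calibration image, ADC map, final-infarct
mask and gray-matter map — from known ground truth, including an MCA lesion
with configurable collateral supply and a peri-lesional transit delay.

## Worked example

```python
import vepasl as v

config = v.PipelineConfig(output_dir="demo", seed=42,
                          phantom=v.PhantomSpec(seed=42))
state = v.run_pipeline(config)   # simulate -> decode -> fit -> maps -> ROIs -> stats
print(state["report"])
```

On the default phantom (64×64×24 voxels of 3.4×3.4×5 mm, collateral
scenario, temporal SNR 5) this prints, among others:

```
indirect_fraction_surviving      = 0.141
indirect_fraction_contralateral  = 0.008
mean_weighted_att_surviving_s    = 1.591
mean_weighted_att_contralateral_s= 1.342
survival_fraction_below_split    = 0.653
survival_fraction_above_split    = 0.991
split_p_value                    = 9.7e-49
```

Reading: in the shell of tissue that survived around the infarct, 14% of
the blood arrived from arteries other than the ipsilateral ICA, against
~1% in the mirrored contralateral region — collateral flow was sustaining
that tissue. Blood also arrived ~0.25 s later there. In the peri-core
region, voxels receiving more than 25 ml/100 g/min of collateral (Indirect)
CBF survived far more often (99% vs 65%), and the per-bin survival table
(`state["survival_table"]`) rises monotonically with Indirect CBF.

The same pipeline runs from the shell:

```bash
vepasl all --output-dir demo --seed 42        # or stage by stage:
vepasl simulate --output-dir demo --seed 42
vepasl decode   --output-dir demo
...
```

All volumes are written as NIfTI with a YAML sidecar describing the
protocol, encoding matrix and volume ordering; tables are CSV.

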