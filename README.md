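# regcg — binding-regularized relative entropy minimization for coarse-grained models

`regcg` builds and trains bottom-up coarse-grained (CG) bead models of
molecular complexes.  It is aimed at people who parametrize CG models of
protein assemblies or nucleic-acid complexes from reference simulations and
have run into the classic failure mode of that workflow: a reference
trajectory of a complex that never dissociates says nothing about the true
binding affinity, so a model trained for distributional consistency keeps
deepening its inter-molecular wells — the complex comes out dramatically
overstabilized.

## The method

A CG configuration `R^N` is scored by

    U = U_bond + U_elec + U_rep + U_att

with intra-monomer harmonic springs (`U_bond`, fitted by a heterogeneous
elastic network, hENM), and three inter-monomer terms per bead pair (I, J):
Debye-screened electrostatics `Q_I Q_J e^(-kappa_D R) / (4 pi eps0 eps_r R)`,
a soft steric shoulder `A_IJ [1 + cos(pi R / R_rep^IJ)]` plus a short-range
`B / R^4` barrier, and a Gaussian well
`C_IJ / (sigma sqrt(2 pi)) * exp(-(R - R_att^IJ)^2 / 2 sigma^2)`.
Bead definitions come from essential-dynamics coarse-graining (EDCG):
contiguous segments chosen to minimize intra-bead fluctuation mismatch in
the principal-component subspace of the reference trajectory.

Only the Gaussian amplitudes `theta = {C_IJ}` are trained.  Standard
relative entropy minimization (REM) descends the Kullback–Leibler
divergence between reference and model ensembles,

    grad L = beta <dU/dtheta>_ref  -  beta <dU/dtheta>_CG ,

re-sampling the CG ensemble with Langevin dynamics each iteration.  The
regularized method (reg-REM) adds a penalty on the mean inter-molecular
binding energy `Vbar_bind`,

    L = D_KL(ref || CG) + kappa (V0 - Vbar_bind)^2 ,

whose gradient only needs the binding energy and dU/dtheta recorded per
sampled frame.  `V0` is an empirical or hypothetical target affinity;
`kappa` can be set by the rule of thumb implemented in
`regcg.kappa_heuristic`.  With `kappa = 0` the method reduces exactly to
standard REM.

The package ships a synthetic-data module (`regcg.fixtures`) that generates
ground-truth reference systems in the three regimes such a method must
handle — a rigidly bound dimer, a C3-symmetric trimer lattice trained
through one designated monomer pair with parameters shared by all monomers,
and a weakly bound chain pair whose terminal rungs fray and which unbinds
and rebinds at elevated temperature.

## Worked example

Train a model from scratch against a synthetic bound-dimer reference whose
true mean binding energy is known, asking for a target of −25 kJ/mol:

```python
import numpy as np
from regcg.fixtures import FixtureSpec, make_dimer_reference, wall_radius_for
from regcg.remtrain import RegConfig, train
from regcg.simulate import SimSettings
from regcg.units import KCAL

ref = make_dimer_reference(FixtureSpec(kind="dimer", n_frames=1000, seed=0))
print(f"reference: {ref.topology.n_beads} beads, "
      f"mean V_bind = {ref.ensemble.v_bind.mean():.2f} kJ/mol")

params = ref.params.copy()
params.set_theta(np.zeros_like(ref.theta_star))   # forget the attractions

config = RegConfig(
    V0=-25.0, kappa_reg=0.1 / KCAL, n_iterations=80,
    sim=SimSettings(temperature=310.0, n_steps=50_000, stride=100,
                    wall_radius=wall_radius_for(ref.spec)),
    seed=1,
)
result = train(ref.topology, params, ref.ensemble, config, native=ref.native)
print(f"final-window mean V_bind = {result.final_window_vbind(20):.2f} kJ/mol")
print(f"final-window mean RMSD   = {result.rmsd_history()[-20:].mean()*10:.2f} A")
```

prints (about a minute on one core):

```
reference: 10 beads, mean V_bind = -25.73 kJ/mol
final-window mean V_bind = -25.15 kJ/mol
final-window mean RMSD   = 1.49 A
```

The trained model hits the requested affinity while the sampled structures
stay within 1.5 Å of the native bound structure — the regularization does
not trade structural accuracy for the affinity target.  Running the same
loop with `kappa_reg=0` shows the overfitting baseline: the binding energy
keeps dropping well past the reference's true −25.7 kJ/mol.

The same workflow is available from the shell:

```bash
regcg fixtures --kind dimer --seed 0 --out-dir fx
regcg analyze  --trajectory fx/reference.xyz --topology fx/topology.tsv --pair P3 Q3 --out rdf.tsv
regcg train    --topology fx/topology.tsv --params fx/params_truth.tsv \
               --reference fx/reference.xyz --config config.yml --out-dir run
```

`regcg map` (EDCG partitioning), `regcg henm` (spring fitting),
`regcg build` (rule-based nonbonded constants) and `regcg simulate` cover
the model-building steps.

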