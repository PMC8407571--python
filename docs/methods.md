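# Methods

## The dendritic normalisation

A sparsely connected artificial neuron stores an unnormalised afferent
weight vector **v** on its existing connections and computes with the
effective weights

    w = e · v / Π_{p ∈ orders} ‖v‖_p

where ‖v‖₀ = n is the in-degree, ‖v‖_p = (Σ|v_j|^p)^{1/p} for p ≥ 1, and
the excitability e is either one trainable scalar s shared by all neurons
of a class (constant mode) or a per-neuron g_i (variable mode).  The
headline scheme is the singleton {0}: dividing afferent strength by
afferent count, which is what a passive dendrite does physically — a
neuron that receives more contacts must maintain a longer dendrite, and
the somatic impact of any one synapse scales as 1/L and hence 1/n.  The
{2} scheme is the heterosynaptic (weight-norm) counterpart; pairs such as
{0,2} multiply both norms in the denominator.

Gradients are the exact chain rule of the cost through this map.  For {0}
this is the scaling ∇_v C = (s/n)∇_w C and ∂C/∂s = Σ_i (1/n_i)∇_{w_i}C·v_i;
for p ≥ 1 the Jacobian term uses sign(v)|v|^{p−1} so signed weights are
handled at every order, including even p.  We validate all eighteen
scheme/mode combinations against central finite differences (≤10⁻⁵
relative).  Two published forms of the variable-excitability gradients
carry an extra factor of g_i relative to the chain rule of their stated
parametrisation; we implement the chain rule, which the finite-difference
oracle confirms and which agrees with the constant-excitability headline
case.  A consequence worth noting: the identity grad_v·v = 0 ("first-order
norm preservation") holds exactly when a scheme contains exactly one
p ≥ 1 order; for a two-norm product like {1,2} the map is homogeneous of
degree −1 and the identity fails by the factor (1 − k), k the number of
p ≥ 1 orders.  The tests assert the general identity.

Excitability parameters start at 1 and are trained by the same SGD step as
the weights.  Each layer (and each input stream of the recurrent network)
is treated as one neuron class with its own s.

## Passive-cable analytics

The dendrite is a sealed passive cylinder of radius r, length l, axial
resistivity r_a, leak conductivity g_l and specific capacitance c, with
electrotonic constants λ = √(r/(2 r_a g_l)), L = l/λ, G∞ = πr²/(λ r_a),
τ_l = c/g_l.  The standard parameter set (r = 1 μm, g_l = 5·10⁻⁵ S/cm²,
r_a = 100 Ω·cm, c = 1 μF/cm²) gives λ = 1 mm and τ_l = 20 ms.  The module
computes, in closed form: the transfer resistance
R_L(X) = cosh(L−X)/(G∞ sinh L), with a lumped-soma load entering as
R_L(X) = cosh(L−X)/[G∞(sinh L + (G_s/G∞)cosh L)], G_s = 4πρ²g_l — the
dimensionally consistent reading, adjudicated against a compartmental
model with an explicit soma compartment; the mean and variance over a
uniformly random synaptic location of the steady somatic response; the
impulse-response cosine-mode series; the transient mean voltage for a
difference-of-exponentials synaptic current; its variance over location;
the peak time t* (bracketed root-finding on the stationarity condition;
t* is independent of L); and the integrated voltage V̄ = Θ_syn τ_l/(2L)
with variance Θ²/(2L²)Σ τ_n², τ_n = τ_l(1+(πn/L)²)⁻¹.

Variances are derived directly from mode orthogonality
(E[cos²(nπX/L)] = 1/2 for X ~ U(0,L)) rather than transcribed: the
printed renderings of the steady and transient variance coefficients are
typographically unreliable, and Monte-Carlo sampling over the synapse
location confirms the derived factors.  Series are truncated when the next
term's bound falls below 10⁻⁹ of the running sum, hard-capped at 10⁴
terms.  Transient responses are expressed in the response-density
convention in which the location-averaged impulse response integrates to
τ_l/(2L); multiplying by 2L/C_tot (C_tot = 2πrlc the total membrane
capacitance) converts to physical millivolts per unit charge, which is how
the compartmental oracle is compared (agreement ≤1%).

The compartmental oracle discretises the cable into ≥200 cylinders
(banded linear solve for steady state, implicit Euler for transients).  It
shares no code with the analytics and exists only for validation.

## Sparse networks, SGD and BPTT

Layers hold v on an explicit boolean mask; gradient descent never changes
the mask.  Initial connectivity is Erdős–Rényi with probability ε and
N(0,1) weights; a neuron left with no afferents receives one random
contact (an empty afferent vector is degenerate under {0}).  Biases start
at zero; minibatch gradients are means over samples (η is then invariant
to minibatch size).  Feedforward classifiers use sigmoid hidden units, a
softmax readout and the log-likelihood cost; η = 0.05, minibatch 10.

The recurrent network for binary addition has two input units, M = 50
sigmoid hidden units with sparse recurrent connectivity (ε = 0.3), and a
single sigmoid output; the cost is the per-step mean squared error of the
raw output, and a sequence scores as accurate only if every rounded bit is
correct.  BPTT is exact over each sequence with hidden state reset at
sequence boundaries, and accumulates per-step gradients over the sequence
(the conventional BPTT sum) while the reported cost keeps the per-step
mean; with the literal per-step-mean in the gradient as well, η = 0.05
moves the cost by ~10⁻⁵ per minibatch and the task is unlearnable on any
realistic schedule.  Addition sequences present the least significant bit
first, so the carry recursion is causal; addends are capped below
2^{m−1} so the sum fits in m bits.

Desk scale: m = 20-bit addends.  Fifty-bit sequences at this learning
rate suffer occasional exploding-gradient collapses through the 50-step
unroll (roughly a third of sparse-feedforward runs lose the solution
entirely), and shorter sequences remove most of that failure mode at 2.5×
less cost.  The sparse-feedforward experiments raise the epoch count to
compensate the reduced per-sequence gradient depth: the reproduction
script runs 250 epochs of 1000 sequences (250·1000·20 = 5·10⁶
step-updates, the reference protocol's exact budget) and the in-suite
check runs 150 epochs for runtime; the dense-feedforward experiments
keep 100 epochs, their connectivity statistic being stationary far
earlier.

## Evolutionary rewiring (SET)

After each epoch the fraction ζ (default 0.15) of weakest contacts in a
pool is excised (⌊ζE⌋ of E, ties broken by a random permutation) and the
same number regrown uniformly among absent pairs with fresh N(0,1)
weights.  "Weakest" defaults to the smallest |effective weight| — the
functional strength, which under {0} makes survival depend on the
neuron's in-degree — with ranking on raw |v| behind a flag.  A pool may
span several streams (the feedforward and recurrent streams of the
sparse-input recurrent network), in which case weak contacts of the two
streams compete; regrowth may land on previously excised pairs.

## Graph analytics

The average shortest path length of a connectivity mask is the mean
directed BFS distance over ordered pairs (i ≠ j), with unreachable pairs
excluded and self-loops ignored; a symmetrised variant sits behind a
flag.  A brute-force Floyd–Warshall oracle checks the implementation on
small graphs.  Degree/weight histograms, per-pixel efferent maps and the
both-input fraction (hidden neurons contacted by both input units of the
recurrent net) are computed directly from the masks; fresh ER layers are
validated against Binomial(fan_in, ε) by a pooled chi-squared test.

## The self-organising network

N_e = 100 excitatory and N_i = 20 inhibitory spiking neurons (the 5:1
ratio of the reservoir-computing literature for this architecture) each
own an equivalent-cylinder passive dendrite; 3-D morphology synthesis is
deliberately replaced by this abstraction, since the normalisation
mechanism depends only on the length–connectivity proportionality and the
transfer resistance along a cable.  Connectivity: 30% of E→E pairs (no
self-connections), 70% of E→I and I→E, no I→I.  Local weight magnitudes
are gamma-distributed; the source recipe is ambiguous (shape 0.2/rate 1
is the explicit density; the quoted mean and sd of 0.2 imply shape 1/rate
5), so a config switch selects the reading, defaulting to shape 0.2/rate
1, and the choice is logged at initialisation.  Synapse locations are
uniform on the postsynaptic dendrite.

Each timestep, the somatic voltage is the transfer-resistance-weighted sum
of currents from afferents that spiked on the previous step; a neuron
spikes above threshold θ.  The stimulus — one letter of the two-word
stream per step — is the unconditional activation of that letter's five
input neurons: the calibrated θ sits near zero on the single-synapse
voltage scale, so any θ-proportional injected current would be swamped by
inhibitory fluctuations, and forced activation is the faithful reading of
a stimulus that "activates" its input group.

E→E synapses undergo soft-bounded pair STDP: potentiation by
η_stdp(synmax − w) for pre-then-post across one step, depression by
η_stdp·w for post-then-pre, keeping w in [0, synmax] without clipping.
Each epoch (default 1000 presentations; desk runs use 300) ends with SET
on the E→E pool (ranked by local weight, regrown with fresh gamma draws)
and excitatory dendrite resizing: l_i ← n_i·(l̄/n̄) with the means taken
before resizing, after which every afferent is relocated uniformly — so
length is exactly proportional to afferent count, by construction, after
every epoch.

θ, synmax and η_stdp are free parameters of the model.  θ is set by a
bisection calibration on the true (plasticity-free) dynamics targeting
7.5% initial excitatory spike probability under stimulus, recorded in the
run manifest.  synmax = 0.15 and η_stdp = 0.02 were chosen so that the
all-firing attractor is not self-sustaining: with pot/dep balance the
plastic weights equilibrate near synmax/2, and the saturated recurrent
drive E_aff·synmax/2 must stay below the static inhibition I_aff·E[w_ie],
which with uncapped gamma inhibitory weights requires synmax ≲ 0.19.
Only the plastic E→E weights are capped at synmax; the static E→I and
I→E weights keep the raw gamma draw.

Performance readout: plasticity is frozen, a dense 30-hidden-unit softmax
classifier is trained (η = 0.05, minibatch 10) to predict the next letter
from the instantaneous excitatory spike vector, and raw accuracy is
rescaled to the normalised score (acc − b)/(m* − b), with
m* = (W − 1/2)/W the best achievable fraction for word length W and
b = Σ f_l² the accuracy of a letter-frequency-matched guesser, both
computed from the stream.  A known property of this score worth keeping
in mind: a memoryless network that merely encodes the current letter
scores (W − 3/2)/W before normalisation, which *approaches* m* as W
grows — so the normalised score of a network without genuine sequence
memory rises with the number of repeated middle letters.  Our desk-scale
network shows genuine memory only at short repeats, and its score curve
over n_rep ∈ {2,4,6,8} is consequently not monotone decreasing; the
corresponding acceptance test records this as a model limitation rather
than being weakened.

The point-neuron control is initialised identically but places every
synapse at a fixed somatic resistance (that of the population's initial
mean-length cable), removing the length–connectivity relation.

## What the synthetic data do and do not emulate

The image generator produces ten smooth random class templates with
centre-weighted contrast plus pixelwise Gaussian noise (sd 0.25, at which
a nearest-template classifier exceeds 90%), emulating the centred,
informative-middle structure of handwritten-digit benchmarks at desk
scale.  It does not emulate within-class style variation, stroke
topology, or label noise; passing results demonstrate the mechanism
(normalised nets keep pre-activations in the sensitive range and learn
faster early), not benchmark-level accuracy.  The binary-addition
generator is exact and unlimited; epochs are a generator parameter (1000
sequences) because the dataset has no natural size.  The word-stream
generator reproduces the two-word grammar exactly; it does not model
stimulus noise or overlapping input populations.

## Numerical choices

Sigmoids are computed in the numerically stable split form; softmax is
max-shifted.  Series truncation as above.  The SET tie-break is a random
permutation, making rewiring a pure function of its RNG.  Degenerate
inputs are rejected loudly: coincident kernel time constants, empty
afferent supports under a p ≥ 1 norm, saturated rewiring pools,
single-letter streams.  All experiment drivers are pure functions of
their parameters and seeds; manifests record every resolved default and
calibrated constant.

## Known limitations

- The recurrent-connectivity restructuring reported for the reference
  experiments (post-training ASPL dropping to ~1.15 under normalisation)
  requires a near-complete isolation of a subset of neurons that our
  dynamics do not produce under any ranking metric or schedule we tested;
  our masks stay statistically Erdős–Rényi (ASPL ≈ 1.71) while the
  in-degree distribution narrows under {0}.  See the acceptance notes.
- The initial-mask ASPL of a directed ER(50, 0.3) graph is 1.707 ± 0.012,
  not the 1.7664 printed in the reference; no convention we tested
  (symmetrisation, included input/output units, alternative density
  readings) reproduces the printed value.
- The simplified spiking network does not learn to count long runs of
  repeated letters; see the score discussion above.
- Threshold-linear hidden units are supported in the feedforward stack
  but the recurrent network is sigmoid-only.
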