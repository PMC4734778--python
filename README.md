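# ilfkit

Design automation for **distributed multicellular logic circuits**. Given any
N-input Boolean function, `ilfkit` compiles a spatial consortium design —
isolated chambers of engineered sensor cells wired by a single secreted
molecule — and verifies the design with a steady-state Hill transfer-function
simulator and digital threshold readout. It is aimed at synthetic biologists
planning consortium-based computations and at anyone studying the resource
scaling of spatially modular biological logic.

## The method

A Boolean function in minimal sum-of-products form, f = Σᵢ Πⱼ φᵢⱼ, is
rewritten by double negation and De Morgan's laws so that each product term
ψᵢ becomes a **NOR** over *inverted* single-input functions
θᵢⱼ = ¬φᵢⱼ. Each θᵢⱼ is realised by one sensor cell: a positive literal xⱼ
maps to a **NOT** cell (secretes the wiring molecule ω when xⱼ is absent), a
negated literal to an **ID** cell (secretes ω when xⱼ is present). All sensor
cells in a chamber share ω — an implicit OR — and ω represses the chamber's
output-layer (OL) cell, so each chamber computes one NOR term; the circuit
output is the OR over chambers, read either as the *maximum* reporter level
across chambers (transducer mode) or through a saturating buffer cell fed by
a pooled secreted output.

Because only cell *placement* changes with the function, the architecture
scales with the number of inputs N, not with circuit complexity:

* **Z = 2N + 1** cell types suffice for every N-input function
  (ID + NOT per input, one OL cell),
* at most **M = 2^(N−1)** chambers are needed (attained by parity),
* while the number of implementable functions is **B = 2^(2^N)**.

Minimization is exact (Quine–McCluskey prime implicants + branch-and-bound
minimum cover, fewest terms then fewest literals). Every cell type is modelled
as a four-parameter Hill curve y(x) = y_low + (y_high − y_low)·xⁿ/(Kⁿ + xⁿ)
(or its repression mirror) in percent positive cells; an integrated readout
above 60% is logic 1, below 20% logic 0, and anything between is
indeterminate (a verification failure).

## Worked example

```sh
$ ilfkit compile --builtin mux4to1
inputs:      6 (PRO, DOX, ALD, aCa, EST, DEX)
outputs:     f
modules:     4
IL types:    8
OL types:    1
BUF types:   0
bounds:      Z=13 M=32 B=18446744073709551616
```

The 6-input multiplexer (2 selector + 4 data inputs) compiles to **4
chambers built from 8 sensor-cell types and one OL type**: each chamber
holds ID cells for the de-selected selector values and a NOT cell for one
data input. Verifying it against all 64 input combinations with the built-in
step-profile library:

```sh
$ ilfkit verify --builtin mux4to1
...
64/64 combinations correct
```

Chamber-level detail for one majority-rule stimulus (DEX and EST present,
PRO absent):

```sh
$ ilfkit simulate --builtin majority3 --bits 110
  module 1 [f]: wire=4.00 beta=84.1%
  module 2 [f]: wire=36.00 beta=5.0%
  module 3 [f]: wire=36.00 beta=5.0%
f: integrated=84.1% state=1
```

Module 1 (the DEX·EST chamber) receives almost no wiring molecule — both of
its NOT sensors are repressed — so its OL reporter rises to 84.1%, above the
60% threshold: the circuit reports 1, i.e. at least two of the three
molecules are present. Other subcommands: `scaling` (the Z/M/B table),
`fit` (Hill fits of dose–response CSVs), `demo` (all three showcase
circuits end-to-end).

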