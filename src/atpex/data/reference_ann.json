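{
 "_comment": "Published reference feedforward network for ultrasound-assisted ATPS extraction of grape-pomace phenolics: 3 inputs (AED W/L, temperature degC, time min) -> yield (mg/g), 8 tansig hidden neurons, purelin output. The matrix layout (three input weights, one hidden bias and one layer weight per published row) is inferred from dimensional necessity. The original input/output scaling was not published; the scaling below is a documented, non-authoritative default: min-max over the experimental ranges for the inputs, identity for the output.",
 "n_hidden": 8,
 "input_weights": [
  [-0.0208, -1.8692, 0.4737],
  [-0.5234, -0.232, -0.3317],
  [-0.0265, -0.0456, 4.5969],
  [0.1863, 0.2145, 0.7919],
  [0.3811, 0.4395, -0.2017],
  [-0.9496, -4.0299, -7.4196],
  [1.0147, -1.9058, -1.1701],
  [4.7435, 2.6728, -0.2655]
 ],
 "hidden_bias": [3.657, 1.9563, 5.4388, 0.4626, 1.4884, 4.7981, -0.5057, 4.7459],
 "layer_weights": [[-0.8835, -1.2199, 2.3043, 0.6161, 1.1, 0.0043, 0.0354, -0.0408]],
 "output_bias": -1.0773,
 "input_scaling": [[41.1, 111.2], [20.0, 40.0], [0.0, 60.0]],
 "output_scaling": "identity",
 "hidden_transfer": "tansig"
}
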