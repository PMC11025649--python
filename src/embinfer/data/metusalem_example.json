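{
  "protocol": "metusalem",
  "provenance": "worked example item of the discourse-inference paradigm (Metusalem et al. design)",
  "items": [
    {
      "item_id": "met-example-1",
      "discourse": "Elizabeth was standing at the intersection waiting for the light to change. All of a sudden she saw a car barrel through the red light.",
      "sentence": "A moment later, she heard a terrible",
      "expected": "crash",
      "related": "policeman",
      "unrelated": "conductor"
    }
  ]
}
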