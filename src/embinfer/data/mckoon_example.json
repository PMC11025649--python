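{
  "protocol": "mckoon",
  "provenance": "worked example item of the word-order inference paradigm (McKoon & Ratcliff design)",
  "items": [
    {
      "item_id": "mckoon-example-1",
      "context_sentence": "The debutante owed a letter to her mother, so she picked up some paper and sat down.",
      "control_sentence": "Like her mother, the debutante lettered in sports and often had her name in the paper.",
      "target": "write"
    }
  ]
}
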