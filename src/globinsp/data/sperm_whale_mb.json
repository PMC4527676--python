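{
  "id": "spermwhale_Mb",
  "description": "Sperm whale myoglobin, mature chain (153 residues), with the standard helix boundaries used for helix-relative position naming (F8 = His93, E7 = His64, CD1 = Phe43).",
  "sequence": "VLSEGEWQLVLHVWAKVEADVAGHGQDILIRLFKSHPETLEKFDRFKHLKTEAEMKASEDLKKHGVTVLTALGAILKKKGHHEAELKPLAQSHATKHKIPIKYLEFISEAIIHVLHSRHPGDFGADAQGAMNKALELFRKDIAAKYKELGYQG",
  "helices": {
    "A": [3, 18],
    "B": [20, 35],
    "C": [36, 42],
    "CD": [43, 49],
    "D": [51, 57],
    "E": [58, 77],
    "EF": [78, 85],
    "F": [86, 94],
    "FG": [95, 99],
    "G": [100, 118],
    "GH": [119, 124],
    "H": [125, 148]
  }
}
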