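# Approximate default layout for shape S (stacked zigzag, 10 cubes).
0 0 0 wood
1 0 0 wood
2 0 0 wood
2 0 1 wood
2 0 2 wood
3 0 2 wood
4 0 2 wood
4 0 3 wood
4 0 4 wood
5 0 4 wood
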