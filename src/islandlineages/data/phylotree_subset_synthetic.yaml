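# Study-clade haplogroup subtree (synthetic fixture).
#
# Covers the mtDNA clades observed in the Yami/Ivatan populations.  The
# B4a1a4 motif (np 4025 + 16360A transversion) and the F1a1d motif
# (nps 16399 and 11380) follow the published survey; all other branch-defining
# variants are illustrative placeholders in Phylotree-style token
# notation against the packaged synthetic reference.  This is explicitly
# not a mirror of the published Phylotree.
name: mt-MRCA
children:
  - name: L3
    variants: ["769", "1018"]
    children:
      - name: M
        variants: ["489", "10400", "14783", "15043"]
        children:
          - name: M7
            variants: ["6455", "9824"]
            children:
              - name: M7b
                variants: ["4164", "16297"]
                children:
                  - name: M7b3
                    variants: ["16234"]
                    children:
                      - name: M7b3a
                        variants: ["12811"]
                  - name: M7b4
                    variants: ["5351"]
              - name: M7c
                variants: ["3606", "16295"]
                children:
                  - name: M7c3
                    variants: ["1888"]
                    children:
                      - name: M7c3a
                        variants: ["11665"]
                      - name: M7c3c
                        variants: ["4850"]
                        children:
                          - name: M7c3c2
                            variants: ["5442"]
          - name: E
            variants: ["10834", "13626"]
            children:
              - name: E1
                variants: ["3027"]
                children:
                  - name: E1a
                    variants: ["6620"]
                    children:
                      - name: E1a1a
                        variants: ["16291"]
              - name: E2
                variants: ["16050"]
                children:
                  - name: E2a
                    variants: ["15071"]
                  - name: E2b
                    variants: ["15850"]
                    children:
                      - name: E2b1
                        variants: ["16153"]
                      - name: E2b2
                        variants: ["12950"]
      - name: N
        variants: ["8701", "15301"]
        children:
          - name: N9
            variants: ["5417"]
            children:
              - name: N9a
                variants: ["16257A"]
                children:
                  - name: N9a10
                    variants: ["12372"]
          - name: R
            variants: ["12705", "16223"]
            children:
              - name: B4'5
                variants: ["8281d", "16189"]
                children:
                  - name: B4
                    variants: ["16217"]
                    children:
                      - name: B4a
                        variants: ["146", "5465"]
                        children:
                          - name: B4a1
                            variants: ["14022"]
                            children:
                              - name: B4a1a
                                variants: ["6719", "16261"]
                                children:
                                  - name: B4a1a4
                                    variants: ["4025", "16360A"]
                          - name: B4a2
                            variants: ["10238"]
                            children:
                              - name: B4a2a
                                variants: ["16216"]
                      - name: B4c
                        variants: ["3497"]
                        children:
                          - name: B4c1
                            variants: ["15346"]
                            children:
                              - name: B4c1b
                                variants: ["16148"]
                                children:
                                  - name: B4c1b2
                                    variants: ["10964"]
                  - name: B5
                    variants: ["8584", "16140"]
                    children:
                      - name: B5b
                        variants: ["85", "16243"]
                        children:
                          - name: B5b1
                            variants: ["204"]
              - name: F
                variants: ["6392", "16304"]
                children:
                  - name: F1
                    variants: ["4086"]
                    children:
                      - name: F1a
                        variants: ["16162"]
                        children:
                          - name: F1a1
                            variants: ["16172"]
                            children:
                              - name: F1a1d
                                variants: ["16399", "11380"]
                          - name: F1a3
                            variants: ["16355"]
                          - name: F1a4
                            variants: ["5263"]
                  - name: F4
                    variants: ["12406"]
                    children:
                      - name: F4b
                        variants: ["10609"]
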